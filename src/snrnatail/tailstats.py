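"""Summary statistics over end calls.

Computes the quantities plotted for targeted 3'-end libraries: cumulative
end-position distributions (solid line = apparent/actual termini, dotted
line = genome-templated termini), percent mature / percent extended /
percent truncated, position-by-base tail-composition matrices (logo-style),
and mean untemplated A or U per transcript — with replicate aggregation as
mean +/- SEM.

All statistics share one filtering rule: only transcripts whose apparent
end lies at or downstream of the window start (default -5) are counted, and
the number excluded is always reported. Statistics can be weighted per
UMI-collapsed molecule (default) or per read.

Definitions of the boundary classes, stated explicitly because they matter:
a transcript is *mature* iff its apparent end is exactly 0 (no templated
extension and no tail), *extended* iff its apparent end is >= +1 (so a
mature-positioned end carrying a 1-nt tail counts as extended), and
*truncated* iff its apparent end is < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from snrnatail.endcall import EndCall

BASES = ("A", "C", "G", "U")

Weighting = Literal["molecule", "read"]


def _weights(calls: Sequence[EndCall], weighting: Weighting) -> np.ndarray:
    if weighting == "molecule":
        return np.ones(len(calls))
    if weighting == "read":
        return np.asarray([c.n_reads for c in calls], dtype=float)
    raise ValueError(f"unknown weighting {weighting!r}")


def in_window(
    calls: Sequence[EndCall], window_start: int = -5
) -> tuple[list[EndCall], int]:
    """Apply the window filter; returns (kept calls, number excluded)."""
    kept = [c for c in calls if c.apparent_end >= window_start]
    return kept, len(calls) - len(kept)


def cumulative_end_distribution(
    calls: Sequence[EndCall],
    mode: Literal["apparent", "templated"] = "apparent",
    window_start: int = -5,
    window_end: int | None = None,
    weighting: Weighting = "molecule",
) -> pd.DataFrame:
    """Cumulative % of transcripts ending at or before each position.

    ``mode="apparent"`` uses the actual 3' terminus including tails (solid
    line); ``mode="templated"`` the genome-encoded end (dotted line). Calls
    terminating upstream of ``window_start`` are excluded (the exclusion
    count is in ``df.attrs["n_excluded"]``); the cumulative fraction reaches
    100% at the last observed position.
    """
    kept, n_excluded = in_window(calls, window_start)
    if not kept:
        raise ValueError("no calls in window")
    ends = np.asarray(
        [c.apparent_end if mode == "apparent" else c.templated_end for c in kept]
    )
    w = _weights(kept, weighting)
    hi = window_end if window_end is not None else int(ends.max())
    positions = np.arange(window_start, hi + 1)
    total = w.sum()
    cum = [100.0 * w[ends <= p].sum() / total for p in positions]
    df = pd.DataFrame({"position": positions, "mode": mode, "cumulative_pct": cum})
    df.attrs["n_excluded"] = n_excluded
    df.attrs["n_in_window"] = len(kept)
    return df


def _pct(calls: Sequence[EndCall], pred, window_start: int, weighting: Weighting) -> float:
    kept, _ = in_window(calls, window_start)
    if not kept:
        raise ValueError("no calls in window")
    w = _weights(kept, weighting)
    hit = np.asarray([pred(c) for c in kept], dtype=bool)
    return float(100.0 * w[hit].sum() / w.sum())


def percent_mature(
    calls: Sequence[EndCall], window_start: int = -5, weighting: Weighting = "molecule"
) -> float:
    """% of in-window transcripts ending exactly at the mature 3' end."""
    return _pct(calls, lambda c: c.apparent_end == 0, window_start, weighting)


def percent_extended(
    calls: Sequence[EndCall], window_start: int = -5, weighting: Weighting = "molecule"
) -> float:
    """% of in-window transcripts with apparent end >= +1."""
    return _pct(calls, lambda c: c.apparent_end >= 1, window_start, weighting)


def percent_truncated(
    calls: Sequence[EndCall], window_start: int = -5, weighting: Weighting = "molecule"
) -> float:
    """% of in-window transcripts with apparent end < 0."""
    return _pct(calls, lambda c: c.apparent_end < 0, window_start, weighting)


def tail_composition_matrix(
    calls: Sequence[EndCall],
    max_pos: int = 8,
    window_start: int = -5,
    weighting: Weighting = "molecule",
    denominator: Literal["all", "tailed"] = "all",
) -> pd.DataFrame:
    """Logo-style matrix: % of transcripts with base b at tail position i.

    Entry (i, b) = 100 x (weight of transcripts whose tail is at least i nt
    long and has base b at position i) / denominator, for i = 1..max_pos.
    With ``denominator="all"`` (default) the denominator is all in-window
    transcripts, so the row sum at position i reads as "% of transcripts
    with >= i posttranscriptional nucleotides" and is nonincreasing in i;
    ``"tailed"`` restricts the denominator to transcripts with a tail.
    """
    kept, _ = in_window(calls, window_start)
    if not kept:
        raise ValueError("no calls in window")
    w = _weights(kept, weighting)
    if denominator == "all":
        denom = w.sum()
    elif denominator == "tailed":
        denom = sum(wi for c, wi in zip(kept, w) if c.tail)
        if denom == 0:
            denom = math.nan
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    mat = np.zeros((max_pos, len(BASES)))
    for c, wi in zip(kept, w):
        for i, b in enumerate(c.tail[:max_pos]):
            if b in BASES:
                mat[i, BASES.index(b)] += wi
    return pd.DataFrame(
        100.0 * mat / denom, index=pd.RangeIndex(1, max_pos + 1, name="tail_pos"), columns=BASES
    )


def mean_tail_base(
    calls: Sequence[EndCall],
    base: str,
    window_start: int = -5,
    weighting: Weighting = "molecule",
) -> float:
    """Mean count of ``base`` in the untemplated tail, per transcript.

    Counts the base anywhere in the tail; tailless transcripts contribute 0.
    """
    if base not in BASES:
        raise ValueError(f"base must be one of {BASES}")
    kept, _ = in_window(calls, window_start)
    if not kept:
        raise ValueError("no calls in window")
    w = _weights(kept, weighting)
    counts = np.asarray([c.tail.count(base) for c in kept], dtype=float)
    return float((counts * w).sum() / w.sum())


@dataclass
class EndProfile:
    """Bundle of per-gene, per-sample summary statistics."""

    gene_id: str
    sample_id: str
    weighting: Weighting
    n_transcripts: int
    n_excluded: int
    pct_mature: float
    pct_extended: float
    pct_truncated: float
    mean_A: float
    mean_U: float
    cum_dist: pd.DataFrame = field(repr=False)
    tail_matrix: pd.DataFrame = field(repr=False)

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "sample_id": self.sample_id,
            "weighting": self.weighting,
            "n_transcripts": self.n_transcripts,
            "n_excluded": self.n_excluded,
            "pct_mature": self.pct_mature,
            "pct_extended": self.pct_extended,
            "pct_truncated": self.pct_truncated,
            "mean_A": self.mean_A,
            "mean_U": self.mean_U,
        }


def compute_profile(
    calls: Sequence[EndCall],
    gene_id: str,
    sample_id: str = "",
    weighting: Weighting = "molecule",
    window_start: int = -5,
    max_tail_pos: int = 8,
) -> EndProfile:
    """All summary statistics for one gene in one sample."""
    gene_calls = [c for c in calls if c.gene_id == gene_id]
    kept, n_excluded = in_window(gene_calls, window_start)
    if not kept:
        raise ValueError(f"no in-window calls for {gene_id}")
    apparent = cumulative_end_distribution(
        gene_calls, "apparent", window_start, weighting=weighting
    )
    templated = cumulative_end_distribution(
        gene_calls, "templated", window_start, weighting=weighting
    )
    cum = pd.concat([apparent, templated], ignore_index=True)
    return EndProfile(
        gene_id=gene_id,
        sample_id=sample_id,
        weighting=weighting,
        n_transcripts=len(kept),
        n_excluded=n_excluded,
        pct_mature=percent_mature(gene_calls, window_start, weighting),
        pct_extended=percent_extended(gene_calls, window_start, weighting),
        pct_truncated=percent_truncated(gene_calls, window_start, weighting),
        mean_A=mean_tail_base(gene_calls, "A", window_start, weighting),
        mean_U=mean_tail_base(gene_calls, "U", window_start, weighting),
        cum_dist=cum,
        tail_matrix=tail_composition_matrix(
            gene_calls, max_tail_pos, window_start, weighting
        ),
    )


def aggregate_replicates(values: Iterable[float]) -> dict:
    """Mean and SEM (= sd / sqrt(n), ddof=1) across independent experiments.

    With a single replicate the SEM is undefined and flagged (NaN +
    ``sem_undefined``).
    """
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("no replicate values")
    out = {"mean": float(v.mean()), "n": n}
    if n < 2:
        out["sem"] = math.nan
        out["flag"] = "sem_undefined"
    else:
        out["sem"] = float(v.std(ddof=1) / math.sqrt(n))
        out["flag"] = ""
    return out
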