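"""RT-qPCR relative quantification, decay normalization and half-life fits.

The ddCt method with multi-control normalization: for each condition,
dCt = mean Ct(target) - mean over controls of mean Ct(control); ddCt is the
difference of dCt between condition and reference, and the relative level is
2^-ddCt (amplification efficiency assumed 2.0 per cycle). Controls are
aggregated by arithmetic mean on the Ct scale, i.e. geometric mean on the
abundance scale — the standard ddCt convention; an abundance-scale
arithmetic mean is available behind a flag.

Transcription shut-off half-lives come from an ordinary least-squares fit of
ln(fraction remaining) on time with free intercept: t_half = ln2 / (-slope).
The fit is exact on noiseless exponentials; a nonnegative slope is reported
as an infinite half-life with a ``no_decay`` flag.

Significance uses the classical equal-variance two-sample Student's t-test
(Welch available as an option), with tiers at p < 0.1 / 0.05 / 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample_id", "condition", "target_id", "replicate", "ct")


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"]
    if not ((ct > 0) & (ct < 45)).all():
        raise ValueError("Ct values must lie in (0, 45)")


@dataclass
class DdctResult:
    target_id: str
    condition: str
    reference_condition: str
    ddct: float
    relative_level: float
    replicate_levels: list[float]
    sem: float


def _mean_ct(table: pd.DataFrame, condition: str, target: str) -> float:
    sel = table[(table["condition"] == condition) & (table["target_id"] == target)]["ct"]
    if sel.empty:
        raise ValueError(f"no Ct rows for target {target!r} in condition {condition!r}")
    return float(sel.mean())


def _control_mean_ct(
    table: pd.DataFrame,
    condition: str,
    controls: Sequence[str],
    control_scale: str,
) -> float:
    per_control = [_mean_ct(table, condition, c) for c in controls]
    if control_scale == "ct":
        return float(np.mean(per_control))
    if control_scale == "abundance":
        # arithmetic mean of 2^-Ct, mapped back to the Ct scale
        return float(-np.log2(np.mean([2.0 ** -ct for ct in per_control])))
    raise ValueError(f"unknown control_scale {control_scale!r}")


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    controls: Sequence[str],
    condition: str,
    reference_condition: str,
    control_scale: str = "ct",
) -> DdctResult:
    """Relative level of ``target`` in ``condition`` vs ``reference_condition``.

    Replicate-level values pair each condition replicate's dCt against the
    reference-condition mean dCt, giving per-replicate relative levels whose
    spread yields the SEM.
    """
    validate_ct_table(table)
    if not controls:
        raise ValueError("at least one control target required")
    dct = {}
    for cond in (condition, reference_condition):
        t_ct = _mean_ct(table, cond, target)
        c_ct = _control_mean_ct(table, cond, controls, control_scale)
        dct[cond] = t_ct - c_ct
    ddct = dct[condition] - dct[reference_condition]

    cond_rows = table[
        (table["condition"] == condition) & (table["target_id"] == target)
    ].sort_values("replicate")
    c_ct_cond = _control_mean_ct(table, condition, controls, control_scale)
    rep_levels = [
        2.0 ** -((float(row.ct) - c_ct_cond) - dct[reference_condition])
        for row in cond_rows.itertuples(index=False)
    ]
    if len(rep_levels) >= 2:
        sem = float(np.std(rep_levels, ddof=1) / math.sqrt(len(rep_levels)))
    else:
        sem = math.nan
    return DdctResult(
        target_id=target,
        condition=condition,
        reference_condition=reference_condition,
        ddct=float(ddct),
        relative_level=float(2.0**-ddct),
        replicate_levels=rep_levels,
        sem=sem,
    )


def ddct_all_targets(
    table: pd.DataFrame,
    controls: Sequence[str],
    condition: str,
    reference_condition: str,
    control_scale: str = "ct",
) -> pd.DataFrame:
    """ddCt for every non-control target in the table."""
    targets = [t for t in table["target_id"].unique() if t not in set(controls)]
    rows = []
    for t in targets:
        r = delta_delta_ct(table, t, controls, condition, reference_condition, control_scale)
        rows.append(
            {
                "target_id": t,
                "condition": condition,
                "reference_condition": reference_condition,
                "ddct": r.ddct,
                "relative_level": r.relative_level,
                "sem": r.sem,
                "n_replicates": len(r.replicate_levels),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decay normalization and half-life

def normalize_decay(
    target_levels: Mapping[float, float] | pd.Series,
    control_levels: Sequence[Mapping[float, float] | pd.Series],
) -> pd.DataFrame:
    """Normalize a raw decay course to stable controls and the 0 time point.

    ``normalized(t) = [target(t) / mean(controls(t))] / [target(0) /
    mean(controls(0))]``; global effects that scale target and controls
    alike cancel. Returns a (time_min, fraction) table with fraction 1 at
    t=0 by construction.
    """
    target = pd.Series(dict(target_levels)).sort_index()
    if 0.0 not in target.index:
        raise ValueError("time 0 required")
    ctrl = pd.concat([pd.Series(dict(c)) for c in control_levels], axis=1)
    ctrl = ctrl.loc[target.index]
    if (ctrl <= 0).any().any():
        raise ValueError("control levels must be positive")
    ratio = target / ctrl.mean(axis=1)
    norm = ratio / ratio.loc[0.0]
    return pd.DataFrame({"time_min": norm.index.to_numpy(), "fraction": norm.to_numpy()})


@dataclass
class HalfLifeFit:
    t_half: float  # minutes; inf when no decay
    slope: float  # per minute, on ln scale
    intercept: float
    r_squared: float
    n_points: int
    no_decay: bool


def fit_half_life(series: pd.DataFrame) -> HalfLifeFit:
    """Half-life from log-linear OLS of a normalized decay series.

    ``series`` needs columns ``time_min`` and ``fraction`` (replicates may
    simply be additional rows at the same time); at least three distinct
    timepoints and strictly positive fractions are required.
    """
    t = np.asarray(series["time_min"], dtype=float)
    f = np.asarray(series["fraction"], dtype=float)
    if (f <= 0).any():
        raise ValueError("fractions must be positive for log-linear fitting")
    if len(np.unique(t)) < 3:
        raise ValueError("at least 3 distinct timepoints required")
    res = stats.linregress(t, np.log(f))
    slope = float(res.slope)
    if slope >= 0:
        return HalfLifeFit(
            t_half=math.inf,
            slope=slope,
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            n_points=len(t),
            no_decay=True,
        )
    return HalfLifeFit(
        t_half=math.log(2) / -slope,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(t),
        no_decay=False,
    )


# ---------------------------------------------------------------------------
# significance

SIGNIFICANCE_TIERS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def significance_tier(p: float) -> str:
    for cutoff, stars in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return stars
    return "ns"


def two_tailed_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
    log2_transform: bool = False,
) -> tuple[float, float]:
    """Two-sample Student's t-test (two-tailed).

    Equal-variance by default, matching the classical test; ``equal_var=
    False`` gives Welch. Zero pooled variance with equal means returns
    (0, 1) rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if log2_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log2 transform requires positive values")
        a, b = np.log2(a), np.log2(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
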