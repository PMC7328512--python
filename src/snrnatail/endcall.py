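"""Split each molecule's 3' terminus into templated end and untemplated tail.

This is the core operation of the pipeline. Given a gene-assigned insert
(anchored at the 5' gene-specific primer, i.e. at the start of the mature
sequence) the caller:

1. aligns the insert against the mature body, substitutions only, tolerating
   up to ``max_body_mismatches`` (sequencing errors inside the body);
2. extends the genome-templated match greedily into the downstream genomic
   sequence, zero mismatches allowed in the extension;
3. reports the remaining unmatched 3' suffix as the untemplated
   (posttranscriptional) tail.

The *maximal-templated rule*: the split always assigns the longest possible
templated prefix. When the first tail nucleotide coincides with the next
genomic base (an A added over an A-rich genomic context, say) the greedy
split absorbs it into the templated extension — a deliberate, conservative
convention shared by untemplated-tail callers, which undercounts tails in
ambiguous contexts rather than guessing. ``call_end_exhaustive`` enumerates
every consistent split and serves as the oracle the greedy caller must
always agree with.

The module is fully deterministic; it contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from snrnatail.refmodel import GeneModel
from snrnatail.readproc import Molecule

UNCALLABLE = "body_unalignable"


@dataclass(frozen=True)
class EndCall:
    """Per-molecule 3'-end call.

    ``templated_end`` is the last genome-matching position (the dotted-line
    end of a cumulative plot); ``apparent_end = templated_end + len(tail)``
    is the actual observed terminus (the solid line). Positions follow the
    mature-end convention: 0 = last mature nucleotide.
    """

    gene_id: str
    templated_end: int
    tail: str
    body_mismatches: int = 0
    flags: frozenset[str] = field(default_factory=frozenset)
    n_reads: int = 1
    barcode: str = ""

    @property
    def apparent_end(self) -> int:
        return self.templated_end + len(self.tail)

    @property
    def is_mature(self) -> bool:
        return self.apparent_end == 0


@dataclass(frozen=True)
class Uncallable:
    gene_id: str
    reason: str = UNCALLABLE
    n_reads: int = 1


def _split_insert(
    insert: str, model: GeneModel, max_body_mismatches: int
) -> tuple[int, int, str] | None:
    """Common body alignment; returns (body_mismatches, last_body_pos, suffix).

    ``last_body_pos`` is the position (mature-end coordinates) of the
    insert's last base if it ends inside the mature body, else 0; ``suffix``
    is the insert portion beyond the mature body. None if unalignable.
    """
    mature = model.mature_seq
    if len(insert) < model.anchor_len:
        return None
    overlap = min(len(insert), len(mature))
    mm = sum(1 for i in range(overlap) if insert[i] != mature[i])
    if mm > max_body_mismatches:
        return None
    if len(insert) <= len(mature):
        return mm, len(insert) - len(mature), ""
    return mm, 0, insert[len(mature):]


def call_end(
    molecule: Molecule,
    model: GeneModel,
    max_body_mismatches: int = 2,
    window_start: int = -5,
) -> EndCall | Uncallable:
    """Greedy maximal-templated end call for one molecule."""
    split = _split_insert(molecule.insert, model, max_body_mismatches)
    if split is None:
        return Uncallable(gene_id=model.gene_id, n_reads=molecule.n_reads)
    mm, last_body_pos, suffix = split
    if not suffix:
        templated_end, tail = last_body_pos, ""
    else:
        downstream = model.downstream_seq
        i = 0
        while i < len(suffix) and i < len(downstream) and suffix[i] == downstream[i]:
            i += 1
        templated_end, tail = i, suffix[i:]
    flags = set()
    if templated_end == len(model.downstream_seq):
        flags.add("hit_reference_cap")
    if mm > 0:
        flags.add(f"body_mismatches:{mm}")
    if templated_end + len(tail) < window_start:
        flags.add("truncated_below_window")
    return EndCall(
        gene_id=model.gene_id,
        templated_end=templated_end,
        tail=tail,
        body_mismatches=mm,
        flags=frozenset(flags),
        n_reads=molecule.n_reads,
        barcode=molecule.barcode,
    )


def call_end_exhaustive(
    molecule: Molecule,
    model: GeneModel,
    max_body_mismatches: int = 2,
    window_start: int = -5,
) -> EndCall | Uncallable:
    """Oracle: enumerate every consistent split, return the maximal-templated one.

    Every split of the post-body suffix into (templated prefix matching the
    downstream genome base-by-base, remainder) is checked; the split with
    the longest templated prefix is returned. Must agree with
    :func:`call_end` on all inputs.
    """
    split = _split_insert(molecule.insert, model, max_body_mismatches)
    if split is None:
        return Uncallable(gene_id=model.gene_id, n_reads=molecule.n_reads)
    mm, last_body_pos, suffix = split
    if not suffix:
        templated_end, tail = last_body_pos, ""
    else:
        downstream = model.downstream_seq
        best = None
        for t in range(min(len(suffix), len(downstream)) + 1):
            if suffix[:t] == downstream[:t]:
                best = t  # keep scanning: maximal t wins
        templated_end, tail = best, suffix[best:]
    flags = set()
    if templated_end == len(model.downstream_seq):
        flags.add("hit_reference_cap")
    if mm > 0:
        flags.add(f"body_mismatches:{mm}")
    if templated_end + len(tail) < window_start:
        flags.add("truncated_below_window")
    return EndCall(
        gene_id=model.gene_id,
        templated_end=templated_end,
        tail=tail,
        body_mismatches=mm,
        flags=frozenset(flags),
        n_reads=molecule.n_reads,
        barcode=molecule.barcode,
    )


def call_molecules(
    molecules: list[Molecule],
    registry,
    max_body_mismatches: int = 2,
    window_start: int = -5,
) -> tuple[list[EndCall], list[Uncallable]]:
    """Call every molecule against its assigned gene model."""
    calls: list[EndCall] = []
    uncallable: list[Uncallable] = []
    for mol in molecules:
        result = call_end(mol, registry[mol.gene_id], max_body_mismatches, window_start)
        if isinstance(result, Uncallable):
            uncallable.append(result)
        else:
            calls.append(result)
    return calls, uncallable


def calls_frame(calls: list[EndCall]) -> pd.DataFrame:
    """Tidy per-molecule end-call table."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "barcode": c.barcode,
                "templated_end": c.templated_end,
                "tail": c.tail,
                "apparent_end": c.apparent_end,
                "flags": ";".join(sorted(c.flags)),
                "n_reads": c.n_reads,
            }
            for c in calls
        ],
        columns=[
            "gene_id",
            "barcode",
            "templated_end",
            "tail",
            "apparent_end",
            "flags",
            "n_reads",
        ],
    )
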