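"""Raw-read processing: adapter parsing, gene assignment, UMI collapse.

Reads from the targeted 3'-end libraries have a fixed layout::

    [insert: gene anchor ... 3' terminus][UMI][barcode][constant adapter][fill]

The constant adapter region is located by its rightmost occurrence with at
most a configured number of mismatches (rightmost, because the insert itself
may contain adapter-like subsequences); the UMI and barcode are then sliced
at fixed offsets to its left, and everything before them is the insert.
Reads that fail any step are rejected with a reason code rather than raising
— rejections are data.

PCR duplicates are collapsed by exact identity of (gene_id, barcode, UMI,
insert). The insert is part of the key: the targeted amplicon design
restricts each gene to a small sequence space, and (UMI, insert) pairs are
far safer against UMI collisions than the UMI alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from snrnatail.refmodel import GeneRegistry

REJECT_REASONS = ("no_adapter", "bad_barcode", "short_insert", "no_gene", "ambiguous_gene")


@dataclass(frozen=True)
class AdapterSpec:
    """Layout of the ligated 3' adapter within a read."""

    const_seq: str  # constant region, RNA alphabet
    umi_len: int = 10
    barcode_len: int = 4
    max_mismatches: int = 1
    min_adapter_overlap: int = 8
    min_insert_len: int = 8


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    gene_id: str | None
    insert: str
    umi: str
    barcode: str


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class Molecule:
    gene_id: str
    insert: str
    umi: str
    barcode: str
    n_reads: int


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _mismatches_capped(a: str, b: str, cap: int) -> int:
    """Mismatch count between equal-length strings, early-exit above cap."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                return n
    return n


def find_adapter(seq: str, spec: AdapterSpec) -> int | None:
    """Rightmost start offset of the constant region, or None.

    A full-length match with <= max_mismatches is preferred; a match
    truncated by the read end is accepted if at least ``min_adapter_overlap``
    bases overlap.
    """
    const = spec.const_seq
    n, k = len(seq), len(const)
    for i in range(n - spec.min_adapter_overlap, -1, -1):
        window = seq[i : i + k]
        if len(window) < spec.min_adapter_overlap:
            continue
        if _mismatches_capped(window, const[: len(window)], spec.max_mismatches) <= spec.max_mismatches:
            return i
    return None


def match_barcode(observed: str, barcode_set: Sequence[str], max_mm: int = 1) -> str | None:
    """Unique barcode within ``max_mm`` mismatches, or None."""
    best, best_d, ties = None, max_mm + 1, 0
    for bc in barcode_set:
        if len(bc) != len(observed):
            continue
        d = hamming(observed, bc)
        if d < best_d:
            best, best_d, ties = bc, d, 1
        elif d == best_d:
            ties += 1
    if best is None or ties > 1:
        return None
    return best


def parse_read(
    read_id: str, seq: str, spec: AdapterSpec, barcode_set: Sequence[str]
) -> ProcessedRead | Rejection:
    """Split one read into insert, UMI and barcode, or reject it."""
    seq = seq.upper().replace("T", "U")
    pos = find_adapter(seq, spec)
    if pos is None:
        return Rejection(read_id, "no_adapter")
    bc_start = pos - spec.barcode_len
    umi_start = bc_start - spec.umi_len
    if umi_start < spec.min_insert_len:
        if bc_start < 0 or umi_start < 0:
            return Rejection(read_id, "no_adapter")
        return Rejection(read_id, "short_insert")
    observed_bc = seq[bc_start:pos]
    barcode = match_barcode(observed_bc, barcode_set, max_mm=1)
    if barcode is None:
        return Rejection(read_id, "bad_barcode")
    return ProcessedRead(
        read_id=read_id,
        gene_id=None,
        insert=seq[:umi_start],
        umi=seq[umi_start:bc_start],
        barcode=barcode,
    )


def assign_gene(
    insert: str, registry: GeneRegistry, max_mismatches: int = 1
) -> str | None | str:
    """Gene whose 5' anchor best matches the insert prefix.

    Returns the gene_id on a unique minimum-distance match within
    ``max_mismatches``; ``"no_gene"`` or ``"ambiguous_gene"`` otherwise
    (reason strings double as rejection codes).
    """
    best_gene, best_d, ties = None, None, 0
    for model in registry:
        if len(insert) < model.anchor_len:
            continue
        d = hamming(insert[: model.anchor_len], model.anchor)
        if best_d is None or d < best_d:
            best_gene, best_d, ties = model.gene_id, d, 1
        elif d == best_d:
            ties += 1
    if best_d is None or best_d > max_mismatches:
        return "no_gene"
    if ties > 1:
        return "ambiguous_gene"
    return best_gene


def deduplicate(reads: Iterable[ProcessedRead]) -> list[Molecule]:
    """Collapse PCR duplicates by exact (gene_id, barcode, umi, insert).

    One Molecule per group with n_reads = group size; output sorted
    lexicographically by key for determinism.
    """
    groups: Counter = Counter()
    for r in reads:
        if r.gene_id is None:
            raise ValueError("deduplicate requires gene-assigned reads")
        groups[(r.gene_id, r.barcode, r.umi, r.insert)] += 1
    return [
        Molecule(gene_id=g, barcode=b, umi=u, insert=ins, n_reads=n)
        for (g, b, u, ins), n in sorted(groups.items())
    ]


@dataclass
class ProcessResult:
    molecules: list[Molecule]
    rejections: list[Rejection]
    n_input: int

    def rejection_summary(self) -> pd.DataFrame:
        counts = Counter(r.reason for r in self.rejections)
        return pd.DataFrame(
            [{"reason": reason, "count": counts.get(reason, 0)} for reason in REJECT_REASONS]
        )

    def molecules_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": m.gene_id,
                    "barcode": m.barcode,
                    "umi": m.umi,
                    "insert": m.insert,
                    "n_reads": m.n_reads,
                }
                for m in self.molecules
            ],
            columns=["gene_id", "barcode", "umi", "insert", "n_reads"],
        )


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def process_reads(
    reads: Iterable[tuple[str, str]],
    registry: GeneRegistry,
    spec: AdapterSpec,
    barcode_set: Sequence[str],
    max_anchor_mismatches: int = 1,
    dedup: bool = True,
) -> ProcessResult:
    """Run parse -> assign -> (optionally) collapse over an iterable of reads."""
    accepted: list[ProcessedRead] = []
    rejections: list[Rejection] = []
    n_input = 0
    for rec in reads:
        read_id, seq = rec[0], rec[1]  # tolerate (id, seq, qual) tuples
        n_input += 1
        parsed = parse_read(read_id, seq, spec, barcode_set)
        if isinstance(parsed, Rejection):
            rejections.append(parsed)
            continue
        gene = assign_gene(parsed.insert, registry, max_anchor_mismatches)
        if gene in ("no_gene", "ambiguous_gene"):
            rejections.append(Rejection(read_id, gene))
            continue
        accepted.append(
            ProcessedRead(
                read_id=parsed.read_id,
                gene_id=gene,
                insert=parsed.insert,
                umi=parsed.umi,
                barcode=parsed.barcode,
            )
        )
    if dedup:
        molecules = deduplicate(accepted)
    else:
        molecules = [
            Molecule(r.gene_id, r.insert, r.umi, r.barcode, 1)
            for r in sorted(accepted, key=lambda r: (r.gene_id, r.barcode, r.umi, r.insert))
        ]
    return ProcessResult(molecules=molecules, rejections=rejections, n_input=n_input)
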