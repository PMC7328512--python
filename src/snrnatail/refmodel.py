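"""Gene models and the mature-3'-end coordinate system.

Every downstream stage measures positions relative to the mature 3' end of
an snRNA/snoRNA: position 0 is the last nucleotide of the mature (fully
processed) RNA, position +k is the k-th genome-encoded nucleotide downstream
of it (left by endonucleolytic cleavage of the nascent transcript), and
position -k lies k nucleotides inside the mature body (a truncated or
partially degraded 3' end).

A :class:`GeneModel` carries the mature sequence, the genomic sequence
immediately downstream of the mature end (the template against which 3'
extensions are matched), the length of the 5' gene-specific primer anchor
used for gene assignment, and a category label. Sequences are stored as RNA
(ACGU); DNA input is converted with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {"major_snRNA", "minor_snRNA", "variant_snRNA", "snoRNA_control", "qpcr_control"}
)

_RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(seq: str, context: str = "") -> str:
    """Uppercase and convert DNA to RNA (T -> U); reject anything else."""
    s = seq.upper()
    if "T" in s:
        s = s.replace("T", "U")
        logger.info("converted T->U in sequence%s", f" ({context})" if context else "")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters {sorted(bad)} in sequence {context!r}")
    return s


@dataclass(frozen=True)
class GeneModel:
    """Mature snRNA sequence plus downstream genomic template.

    Parameters
    ----------
    gene_id:
        Unique identifier within a registry.
    mature_seq:
        Mature RNA sequence 5'->3' (ACGU).
    downstream_seq:
        Genome-encoded sequence 3' of the mature end (ACGU). Its length is
        the hard cap on the templated extension that can be called.
    anchor_len:
        Length of the 5' gene-specific primer region used for gene
        assignment; must not exceed the mature length.
    category:
        One of ``major_snRNA``, ``minor_snRNA``, ``variant_snRNA``,
        ``snoRNA_control``, ``qpcr_control``.
    """

    gene_id: str
    mature_seq: str
    downstream_seq: str
    anchor_len: int
    category: str = "major_snRNA"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        for name in ("mature_seq", "downstream_seq"):
            seq = getattr(self, name)
            if not seq:
                raise ValueError(f"{name} must be nonempty for {self.gene_id}")
            object.__setattr__(self, name, normalize_rna(seq, f"{self.gene_id}.{name}"))
        if not 1 <= self.anchor_len <= len(self.mature_seq):
            raise ValueError(
                f"anchor_len {self.anchor_len} out of range for {self.gene_id} "
                f"(mature length {len(self.mature_seq)})"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.gene_id}")

    @property
    def anchor(self) -> str:
        """The 5' anchor: first ``anchor_len`` nt of the amplified mature segment."""
        return self.mature_seq[: self.anchor_len]

    @property
    def mature_len(self) -> int:
        return len(self.mature_seq)

    @property
    def max_extension(self) -> int:
        """Longest templated extension callable against this model."""
        return len(self.downstream_seq)


def genomic_base_at(model: GeneModel, p: int) -> str:
    """Genome-templated base at position ``p`` relative to the mature 3' end.

    ``p = 0`` is the last mature nucleotide, ``p = -k`` lies inside the
    mature body, ``p = +k`` is the k-th downstream genomic base. Valid for
    ``-mature_len < p <= max_extension``.
    """
    if p <= 0:
        idx = len(model.mature_seq) + p - 1
        if idx < 0:
            raise IndexError(f"position {p} upstream of mature sequence of {model.gene_id}")
        return model.mature_seq[idx]
    if p > len(model.downstream_seq):
        raise IndexError(
            f"position {p} beyond downstream reference of {model.gene_id} "
            f"(length {len(model.downstream_seq)})"
        )
    return model.downstream_seq[p - 1]


class GeneRegistry:
    """Mapping of gene_id -> :class:`GeneModel` with uniqueness enforced."""

    def __init__(self, models: list[GeneModel] | None = None) -> None:
        self._models: Dict[str, GeneModel] = {}
        for m in models or []:
            self.add(m)

    def add(self, model: GeneModel) -> None:
        if model.gene_id in self._models:
            raise ValueError(f"duplicate gene_id {model.gene_id!r}")
        self._models[model.gene_id] = model

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._models[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._models.values())

    def __len__(self) -> int:
        return len(self._models)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneRegistry):
            return NotImplemented
        return self._models == other._models

    @property
    def gene_ids(self) -> list[str]:
        return list(self._models)


def load_gene_models(fasta_path: str | Path, annotation_path: str | Path) -> GeneRegistry:
    """Build a registry from a FASTA of mature sequences and a TSV annotation.

    The annotation must be tab-delimited with a header row carrying at least
    ``gene_id``, ``downstream_seq``, ``anchor_len`` and ``category``. Every
    FASTA record must have exactly one annotation row and vice versa;
    duplicate ids on either side are rejected.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "downstream_seq", "anchor_len", "category"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate annotation rows for {dups}")

    registry = GeneRegistry()
    annotated = set(ann["gene_id"])
    unannotated = set(seqs) - annotated
    if unannotated:
        raise ValueError(f"FASTA records without annotation: {sorted(unannotated)}")
    for row in ann.itertuples(index=False):
        if row.gene_id not in seqs:
            raise ValueError(f"annotation row {row.gene_id!r} has no FASTA record")
        registry.add(
            GeneModel(
                gene_id=row.gene_id,
                mature_seq=seqs[row.gene_id],
                downstream_seq=str(row.downstream_seq),
                anchor_len=int(row.anchor_len),
                category=str(row.category),
            )
        )
    logger.info("loaded %d gene models from %s", len(registry), fasta_path)
    return registry
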