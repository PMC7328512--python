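"""Synthetic-data generator for the 3'-end sequencing analysis.

Emulates the library chemistry of a targeted, ligation-based snRNA 3'-end
amplicon protocol: each RNA molecule is a 5'-anchored amplicon running from
the gene-specific forward primer through the 3' terminus into a ligated
adapter that carries a random mer (UMI), a sample barcode and a constant
linker region. Molecules carry a genome-encoded 3' end drawn from a
configurable position distribution, optionally an untemplated tail with
per-position nucleotide composition, and are emitted as PCR duplicates with
per-base substitution error. Ground truth is returned alongside the reads so
the full pipeline can be tested for exact recovery.

The module also generates the two table inputs of the quantification stage:
qPCR cycle-threshold tables built by inverting the ddCt model, and
transcription shut-off decay time courses following exponential decay with
multiplicative lognormal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from snrnatail.refmodel import GeneModel, GeneRegistry

BASES = ("A", "C", "G", "U")
_RNA_TO_DNA = str.maketrans("U", "T")


# ---------------------------------------------------------------------------
# distributions

def _check_dist(dist: Mapping, name: str) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} contains negative probabilities")


def _sample_dist(rng: np.random.Generator, dist: Mapping, size: int) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=size, p=probs / probs.sum())
    return np.asarray(keys, dtype=object)[idx]


def geometric_len_dist(mean: float, max_len: int = 20) -> dict[int, float]:
    """Truncated geometric distribution over tail lengths 1..max_len.

    ``mean`` is the untruncated geometric mean (support starting at 1);
    the tail mass beyond ``max_len`` is renormalized away.
    """
    if mean < 1:
        raise ValueError("geometric mean length must be >= 1")
    p = 1.0 / mean
    raw = {k: p * (1 - p) ** (k - 1) for k in range(1, max_len + 1)}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


# ---------------------------------------------------------------------------
# library simulation

@dataclass
class LibrarySimConfig:
    """Parameters of a simulated 3'-end amplicon library.

    ``end_dist`` is a categorical distribution over genome-encoded end
    positions relative to the mature 3' end (0 = mature, +k = templated
    extension, -k = truncation). ``tail_comp`` is either a single mapping of
    base -> probability applied at every tail position, or a list of such
    mappings (position 1 first; the last entry is reused beyond the list).
    """

    n_molecules: int = 10_000
    end_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    tail_prob: float = 0.0
    tail_len_dist: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    tail_comp: Mapping[str, float] | Sequence[Mapping[str, float]] = field(
        default_factory=lambda: {"A": 1.0}
    )
    seq_error: float = 0.0
    pcr_dup_dist: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    umi_len: int = 10
    barcode: str = "ACGU"
    read_len: int = 150
    const_adapter: str = "AGAUCGGAAGAGCACACGUCU"
    qual_char: str = "I"
    tail_on_truncated: bool = False
    seed: int = 0

    def validate(self) -> None:
        _check_dist(self.end_dist, "end_dist")
        _check_dist(self.tail_len_dist, "tail_len_dist")
        _check_dist(self.pcr_dup_dist, "pcr_dup_dist")
        for comp in self._tail_comp_list():
            _check_dist(comp, "tail_comp")
        if not 0.0 <= self.seq_error <= 0.1:
            raise ValueError("seq_error must be in [0, 0.1]")
        if self.umi_len not in (10, 11):
            raise ValueError("umi_len must be 10 or 11")
        if any(k < 1 for k in self.tail_len_dist):
            raise ValueError("tail lengths must be positive")
        if any(k < 1 for k in self.pcr_dup_dist):
            raise ValueError("duplicate counts must be >= 1")

    def _tail_comp_list(self) -> list[Mapping[str, float]]:
        if isinstance(self.tail_comp, Mapping):
            return [self.tail_comp]
        return list(self.tail_comp)

    def comp_at(self, pos: int) -> Mapping[str, float]:
        """Base composition at tail position ``pos`` (1-based)."""
        comps = self._tail_comp_list()
        return comps[min(pos - 1, len(comps) - 1)]


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[rng.integers(len(alts))]
    return "".join(chars)


def molecule_insert(model: GeneModel, end: int, tail: str) -> str:
    """RNA insert of a molecule: mature body to ``end`` plus untemplated tail."""
    if end < 0:
        body = model.mature_seq[: len(model.mature_seq) + end]
    else:
        if end > len(model.downstream_seq):
            raise ValueError(
                f"end {end} exceeds downstream reference of {model.gene_id}"
            )
        body = model.mature_seq + model.downstream_seq[:end]
    return body + tail


def simulate_library(
    registry: GeneRegistry, config: LibrarySimConfig
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate a FASTQ library and its ground truth.

    Returns ``(reads, truth)`` where each read is a ``(read_id, sequence,
    quality)`` tuple in DNA alphabet and ``truth`` has one row per molecule
    (pre-PCR) with columns ``molecule_id, gene_id, true_end, true_tail,
    n_duplicates, umi, barcode``. Each molecule is emitted ``n_duplicates``
    times with an identical UMI; substitution errors are applied per read.
    Output is deterministic for a fixed seed.
    """
    config.validate()
    max_end = max(config.end_dist)
    for model in registry:
        if max_end > len(model.downstream_seq):
            raise ValueError(
                f"end_dist reaches +{max_end} but {model.gene_id} has only "
                f"{len(model.downstream_seq)} downstream nt"
            )
    min_fixed = len(config.barcode) + config.umi_len
    if config.read_len < min_fixed + 1:
        raise ValueError("read_len too short to contain UMI and barcode")

    rng = np.random.default_rng(config.seed)
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    mol_counter = 0
    for model in sorted(registry, key=lambda m: m.gene_id):
        ends = _sample_dist(rng, config.end_dist, config.n_molecules).astype(int)
        dups = _sample_dist(rng, config.pcr_dup_dist, config.n_molecules).astype(int)
        has_tail = rng.random(config.n_molecules) < config.tail_prob
        for i in range(config.n_molecules):
            end = int(ends[i])
            tail = ""
            if has_tail[i] and (end >= 0 or config.tail_on_truncated):
                tlen = int(_sample_dist(rng, config.tail_len_dist, 1)[0])
                tail = "".join(
                    str(_sample_dist(rng, config.comp_at(j + 1), 1)[0])
                    for j in range(tlen)
                )
            umi = _random_seq(rng, config.umi_len)
            insert = molecule_insert(model, end, tail)
            template = (insert + umi + config.barcode + config.const_adapter).translate(
                _RNA_TO_DNA
            )
            if len(template) > config.read_len:
                template = template[: config.read_len]
            else:
                template = template + "A" * (config.read_len - len(template))
            mol_id = f"mol{mol_counter:07d}"
            n_dup = int(dups[i])
            for d in range(n_dup):
                seq = _apply_errors(rng, template, config.seq_error)
                reads.append((f"{mol_id}_d{d}", seq, config.qual_char * len(seq)))
            truth_rows.append(
                {
                    "molecule_id": mol_id,
                    "gene_id": model.gene_id,
                    "true_end": end,
                    "true_tail": tail,
                    "n_duplicates": n_dup,
                    "umi": umi,
                    "barcode": config.barcode,
                }
            )
            mol_counter += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "molecule_id",
            "gene_id",
            "true_end",
            "true_tail",
            "n_duplicates",
            "umi",
            "barcode",
        ],
    )
    return reads, truth


def expected_call_from_truth(
    model: GeneModel, true_end: int, true_tail: str
) -> tuple[int, str]:
    """Ambiguity-adjusted expected end call for an error-free molecule.

    The maximal-templated split absorbs leading tail bases that coincide with
    the next genomic base into the templated extension; this enumerates that
    adjustment from ground truth, giving the ``(templated_end, tail)`` a
    greedy caller must report.
    """
    if true_end < 0:
        # a tail on a truncated end is indistinguishable from body mismatches
        return (true_end + len(true_tail), "") if true_tail else (true_end, "")
    end = true_end
    j = 0
    while (
        j < len(true_tail)
        and end < len(model.downstream_seq)
        and true_tail[j] == model.downstream_seq[end]
    ):
        end += 1
        j += 1
    return end, true_tail[j:]


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(id, seq, qual)`` tuples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# decay and qPCR table simulation

def simulate_decay_series(
    t_half: float,
    timepoints: Sequence[float] = (0.0, 10.0, 20.0, 30.0),
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    target_id: str = "target",
) -> pd.DataFrame:
    """Simulate a transcription shut-off time course.

    Fraction remaining follows ``exp(-ln2 * t / t_half)`` with multiplicative
    lognormal noise of coefficient of variation ``noise_cv``; each replicate
    is renormalized to its own 0-time value, so fraction at t=0 is exactly 1.
    Returns a tidy table (target_id, replicate, time_min, fraction).
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    timepoints = [float(t) for t in timepoints]
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints)
    rows = []
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    for r in range(n_replicates):
        clean = np.exp(-math.log(2) * t / t_half)
        if sigma > 0:
            noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=len(t))
            values = clean * noise
        else:
            values = clean
        values = values / values[timepoints.index(0.0)]
        for tp, v in zip(timepoints, values):
            rows.append(
                {"target_id": target_id, "replicate": r, "time_min": tp, "fraction": v}
            )
    return pd.DataFrame(rows)


def simulate_ct_table(
    true_fold_changes: Mapping[str, float],
    control_targets: Sequence[str],
    base_ct: float = 20.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str = "treated",
    reference_condition: str = "reference",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table by inverting the ddCt model.

    In the reference condition every target has abundance 1; in ``condition``
    each target in ``true_fold_changes`` has that fold change while controls
    stay at 1 (unless explicitly listed). ``Ct = base_ct - log2(abundance) +
    N(0, ct_noise_sd)``, so with zero noise the downstream ddCt analysis
    recovers the configured fold changes exactly.
    """
    if not control_targets:
        raise ValueError("at least one control target required")
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    targets = list(dict.fromkeys(list(true_fold_changes) + list(control_targets)))
    rows = []
    for cond in (reference_condition, condition):
        for target in targets:
            if cond == reference_condition:
                abundance = 1.0
            else:
                abundance = float(true_fold_changes.get(target, 1.0))
            for r in range(n_replicates):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": f"{cond}_r{r}",
                        "condition": cond,
                        "target_id": target,
                        "replicate": r,
                        "ct": base_ct - math.log2(abundance) + noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy gene models and condition presets

def toy_registry(ambiguity_free: bool = False) -> GeneRegistry:
    """Three synthetic gene models for simulations and fixtures.

    Sequences are synthetic (generated from a fixed internal seed), not real
    snRNA genes. With ``ambiguity_free=True`` the downstream genomic
    sequences contain only C and G, so A/U tails can never coincide with the
    next genomic base and the greedy split is exact.
    """
    rng = np.random.default_rng(20220415)
    models = []
    for gene_id, category in (
        ("U1syn", "major_snRNA"),
        ("U2syn", "major_snRNA"),
        ("U12syn", "minor_snRNA"),
    ):
        mature = _random_seq(rng, 60)
        downstream = _random_seq(rng, 20, "CG" if ambiguity_free else "ACGU")
        models.append(
            GeneModel(
                gene_id=gene_id,
                mature_seq=mature,
                downstream_seq=downstream,
                anchor_len=12,
                category=category,
            )
        )
    return GeneRegistry(models)


#: Condition presets emulating the qualitative regimes of the assay:
#: with the TOE1 deadenylase present, nascent snRNA 3' ends sit at or near
#: the mature position and carry few tails; with TOE1 depleted, genome-
#: encoded extensions persist and A-rich posttranscriptional tails
#: accumulate; degradation-prone variant snRNAs carry mixed A/U tails and a
#: low fraction of mature-length molecules.
PRESETS: dict[str, LibrarySimConfig] = {
    "toe1_plus": LibrarySimConfig(
        n_molecules=5000,
        end_dist={-2: 0.03, -1: 0.07, 0: 0.70, 1: 0.12, 2: 0.05, 3: 0.03},
        tail_prob=0.10,
        tail_len_dist=geometric_len_dist(2.0, 12),
        tail_comp={"A": 0.90, "U": 0.04, "C": 0.03, "G": 0.03},
        pcr_dup_dist={1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        barcode="ACGU",
    ),
    "toe1_minus": LibrarySimConfig(
        n_molecules=5000,
        end_dist={-1: 0.03, 0: 0.22, 1: 0.25, 2: 0.25, 3: 0.15, 4: 0.10},
        tail_prob=0.50,
        tail_len_dist=geometric_len_dist(3.0, 12),
        tail_comp={"A": 0.85, "U": 0.05, "C": 0.05, "G": 0.05},
        pcr_dup_dist={1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        barcode="CAGU",
    ),
    "variant_u1": LibrarySimConfig(
        n_molecules=5000,
        end_dist={-2: 0.05, -1: 0.10, 0: 0.15, 1: 0.25, 2: 0.25, 3: 0.20},
        tail_prob=0.60,
        tail_len_dist=geometric_len_dist(3.0, 12),
        tail_comp={"A": 0.45, "U": 0.45, "C": 0.05, "G": 0.05},
        pcr_dup_dist={1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        barcode="GUCA",
    ),
}


def preset_config(name: str, seed: int = 0, **overrides) -> LibrarySimConfig:
    """A copy of a named preset with the given seed and field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)
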