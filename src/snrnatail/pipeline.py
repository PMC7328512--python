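"""End-to-end orchestration: config, pipeline run, fixture presets.

A run reads a YAML config naming the gene models, the FASTQ input and the
thresholds, executes read processing -> end calling -> statistics (and the
quantification stages when Ct / decay tables are supplied), and writes all
result tables plus an audit of rejections and flags into the output
directory. The config is echoed verbatim next to the results, all
randomness flows from the single named seed, and a rerun with the same
config and inputs is byte-identical for every non-log output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from snrnatail import __version__
from snrnatail.endcall import call_molecules, calls_frame
from snrnatail.quant import ddct_all_targets, fit_half_life
from snrnatail.readproc import AdapterSpec, iter_fastq, process_reads
from snrnatail.refmodel import GeneRegistry, load_gene_models
from snrnatail.simulate import (
    PRESETS,
    preset_config,
    simulate_library,
    toy_registry,
    write_fastq,
)
from snrnatail.tailstats import compute_profile

logger = logging.getLogger(__name__)

DEFAULT_ADAPTER = "AGAUCGGAAGAGCACACGUCU"


@dataclass
class RunConfig:
    gene_fasta: str
    gene_annotation: str
    fastq: str
    output_dir: str
    barcode_samples: Mapping[str, str] = field(default_factory=dict)
    adapter_const: str = DEFAULT_ADAPTER
    umi_len: int = 10
    barcode_len: int = 4
    max_adapter_mm: int = 1
    max_anchor_mm: int = 1
    max_body_mismatches: int = 2
    window_start: int = -5
    tail_matrix_depth: int = 8
    weighting: str = "molecule"
    dedup: bool = True
    ct_table: str | None = None
    ct_controls: list[str] = field(default_factory=list)
    ct_condition: str | None = None
    ct_reference_condition: str | None = None
    decay_table: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for the audit trail."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    registry = load_gene_models(config.gene_fasta, config.gene_annotation)

    spec = AdapterSpec(
        const_seq=config.adapter_const,
        umi_len=config.umi_len,
        barcode_len=config.barcode_len,
        max_mismatches=config.max_adapter_mm,
    )
    barcodes = list(config.barcode_samples) or [""]
    reads = list(iter_fastq(config.fastq))
    if not reads:
        raise PipelineError("readproc", f"no reads in {config.fastq}")
    result = process_reads(
        reads,
        registry,
        spec,
        barcodes,
        max_anchor_mismatches=config.max_anchor_mm,
        dedup=config.dedup,
    )
    _write_tsv(result.molecules_frame(), out / "molecules.tsv")
    _write_tsv(result.rejection_summary(), out / "rejections.tsv")

    calls, uncallable = call_molecules(
        result.molecules,
        registry,
        max_body_mismatches=config.max_body_mismatches,
        window_start=config.window_start,
    )
    if not calls:
        raise PipelineError("endcall", "no callable molecules")
    _write_tsv(calls_frame(calls), out / "endcalls.tsv")

    sample_of = dict(config.barcode_samples)
    profile_rows, cum_frames, mat_frames = [], [], []
    audit_rows = []
    for gene_id in sorted({c.gene_id for c in calls}):
        for barcode in sorted({c.barcode for c in calls if c.gene_id == gene_id}):
            subset = [c for c in calls if c.gene_id == gene_id and c.barcode == barcode]
            sample_id = sample_of.get(barcode, barcode)
            try:
                profile = compute_profile(
                    subset,
                    gene_id,
                    sample_id=sample_id,
                    weighting=config.weighting,  # type: ignore[arg-type]
                    window_start=config.window_start,
                    max_tail_pos=config.tail_matrix_depth,
                )
            except ValueError as exc:
                raise PipelineError("tailstats", f"{gene_id}/{sample_id}: {exc}") from exc
            profile_rows.append(profile.as_row())
            cum = profile.cum_dist.copy()
            cum.insert(0, "sample_id", sample_id)
            cum.insert(0, "gene_id", gene_id)
            cum_frames.append(cum)
            mat = profile.tail_matrix.reset_index()
            mat.insert(0, "sample_id", sample_id)
            mat.insert(0, "gene_id", gene_id)
            mat_frames.append(mat)
            audit_rows.append(
                {
                    "gene_id": gene_id,
                    "sample_id": sample_id,
                    "n_excluded_below_window": profile.n_excluded,
                    "n_uncallable": sum(
                        1 for u in uncallable if u.gene_id == gene_id
                    ),
                }
            )
    _write_tsv(pd.DataFrame(profile_rows), out / "profiles.tsv")
    _write_tsv(pd.concat(cum_frames, ignore_index=True), out / "cumulative_dist.tsv")
    _write_tsv(pd.concat(mat_frames, ignore_index=True), out / "tail_matrix.tsv")
    _write_tsv(pd.DataFrame(audit_rows), out / "audit.tsv")

    summary = {
        "n_input_reads": result.n_input,
        "n_molecules": len(result.molecules),
        "n_rejected": len(result.rejections),
        "n_calls": len(calls),
        "n_uncallable": len(uncallable),
        "outputs": sorted(p.name for p in out.iterdir()),
    }

    if config.ct_table:
        if not (config.ct_controls and config.ct_condition and config.ct_reference_condition):
            raise PipelineError("quant", "ct_table given without controls/conditions")
        table = pd.read_csv(config.ct_table, sep="\t")
        ddct = ddct_all_targets(
            table, config.ct_controls, config.ct_condition, config.ct_reference_condition
        )
        _write_tsv(ddct, out / "ddct.tsv")
        summary["n_ddct_targets"] = len(ddct)

    if config.decay_table:
        decay = pd.read_csv(config.decay_table, sep="\t")
        rows = []
        for target, grp in decay.groupby("target_id"):
            fit = fit_half_life(grp)
            rows.append(
                {
                    "target_id": target,
                    "t_half_min": fit.t_half,
                    "r_squared": fit.r_squared,
                    "no_decay": fit.no_decay,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "half_lives.tsv")
        summary["n_half_lives"] = len(rows)

    with open(out / "run.log", "w") as fh:
        fh.write(f"snrnatail {__version__}\n")
        cfg_hash = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()
        fh.write(f"config_sha256 {cfg_hash}\n")
        for k, v in summary.items():
            fh.write(f"{k} {v}\n")
    return summary


def make_fixtures(preset: str, seed: int, outdir: str | Path) -> Path:
    """Write a simulated fixture set (FASTQ, ground truth, expected stats).

    Presets encode the assay's qualitative regimes: deadenylase present
    (near-mature ends, few tails), deadenylase depleted (persistent
    extensions, A-rich tails) and unstable variant snRNAs (mixed A/U tails,
    low mature fraction).
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = toy_registry()
    config = preset_config(preset, seed=seed)
    reads, truth = simulate_library(registry, config)
    write_fastq(reads, outdir / f"{preset}.fastq")
    _write_tsv(truth, outdir / f"{preset}_truth.tsv")

    # expected statistics straight from ground truth (molecule-weighted)
    rows = []
    for gene_id, grp in truth.groupby("gene_id"):
        apparent = grp["true_end"] + grp["true_tail"].str.len()
        in_win = grp[apparent >= -5]
        app_w = apparent[in_win.index]
        rows.append(
            {
                "gene_id": gene_id,
                "pct_mature": 100.0 * (app_w == 0).mean(),
                "pct_extended": 100.0 * (app_w >= 1).mean(),
                "mean_A": in_win["true_tail"].str.count("A").mean(),
                "mean_U": in_win["true_tail"].str.count("U").mean(),
            }
        )
    _write_tsv(pd.DataFrame(rows), outdir / f"{preset}_expected_stats.tsv")

    write_gene_models(registry, outdir)
    return outdir


def write_gene_models(registry: GeneRegistry, outdir: str | Path) -> tuple[Path, Path]:
    """Serialize a registry as the FASTA + TSV pair load_gene_models reads."""
    outdir = Path(outdir)
    fasta = outdir / "genes.fasta"
    ann = outdir / "genes.tsv"
    with open(fasta, "w") as fh:
        for model in sorted(registry, key=lambda m: m.gene_id):
            fh.write(f">{model.gene_id}\n{model.mature_seq}\n")
    pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "downstream_seq": m.downstream_seq,
                "anchor_len": m.anchor_len,
                "category": m.category,
            }
            for m in sorted(registry, key=lambda m: m.gene_id)
        ]
    ).to_csv(ann, sep="\t", index=False, lineterminator="\n")
    return fasta, ann
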