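# snrnatail

Analysis pipeline for targeted snRNA 3′-end sequencing: per-molecule
classification of 3′ termini into genome-templated extensions and
untemplated (posttranscriptional) tails, with the downstream maturation and
adenylation statistics, RT-qPCR ΔΔCt quantification, and transcription
shut-off half-life estimation.

## The problem

Spliceosomal snRNAs (U1, U2, U4, U5, U11, U12, U4atac) are transcribed with
genome-encoded 3′ extensions that are trimmed back to the mature end during
biogenesis; along the way molecules acquire untemplated oligo(A) (and, for
unstable variants, mixed A/U) tails added by nucleotidyltransferases and
removed by deadenylases such as TOE1. Targeted 3′-end amplicon sequencing —
a gene-specific forward primer through the 3′ terminus into a ligated
adapter carrying a sample barcode and a 10–11-nt random mer (UMI) — reads
out exactly where each molecule ends and what was added to it.

The analytical crux is the **templated/untemplated split**. Writing the
position of the mature 3′ end as 0, an observed 3′ terminus decomposes as

- `templated_end` *e* — the last position matching the genomic sequence
  (negative: truncated into the mature body; positive: genome-encoded
  extension), and
- `tail` *τ* — the remaining untemplated suffix, so the apparent terminus
  is *e* + |τ|.

The caller uses the **greedy maximal-templated rule**: extend the genomic
match as far as it goes (zero mismatches in the extension), then call the
remainder a tail. When the first tail base equals the next genomic base the
two splits are indistinguishable and the rule conservatively under-counts
the tail — a documented, testable bias, verified against an exhaustive
split-enumeration oracle.

From the calls, the package computes cumulative end-position distributions
(apparent vs. templated), % mature (apparent end exactly 0), % extended
(apparent end ≥ +1), logo-style tail composition matrices (% of transcripts
with base *b* at tail position *i*, *i* = 1..8), and mean untemplated A/U
per transcript, with replicate aggregation (mean ± SEM, Student's
two-tailed *t*). qPCR tables are quantified by ΔΔCt (relative level =
2^−ΔΔCt against the averaged controls) and shut-off time courses are fitted
by log-linear OLS, *t*₁/₂ = ln 2 / (−slope).

A synthetic-data generator reproduces the library chemistry end to end —
anchored amplicons, configurable end distributions and tail composition,
UMI/barcode adapter layout, PCR duplication, sequencing error — with ground
truth, so every stage is testable without any external data.

## Worked example

```python
from snrnatail.simulate import toy_registry, preset_config, simulate_library
from snrnatail.readproc import AdapterSpec, process_reads
from snrnatail.endcall import call_molecules
from snrnatail.tailstats import compute_profile

reg = toy_registry()                                  # 3 synthetic gene models
cfg = preset_config("toe1_minus", seed=1, n_molecules=2000)
reads, truth = simulate_library(reg, cfg)             # FASTQ + ground truth
spec = AdapterSpec(const_seq=cfg.const_adapter, umi_len=cfg.umi_len,
                   barcode_len=len(cfg.barcode))
res = process_reads(reads, reg, spec, [cfg.barcode])  # parse, assign, dedup
calls, _ = call_molecules(res.molecules, reg)         # templated/tail split
profile = compute_profile(calls, "U1syn", sample_id="toe1_minus")
```

which prints, for the deadenylase-depleted preset:

```
reads in: 11963, molecules: 6000
pct_mature   = 10.8%
pct_extended = 85.8%
mean A / transcript = 1.22
             A    C    G    U
tail_pos
1         41.8  1.2  2.0  2.0
2         26.9  1.9  1.4  1.6
3         18.1  1.2  0.7  0.8
```

Read: 11,963 reads collapsed to exactly the 6,000 simulated molecules
(2,000 per gene); under depletion of the trimming deadenylase only ~11% of
U1 molecules end at the mature position, ~86% are 3′ extended, molecules
carry on average 1.2 untemplated adenosines, and 41.8% of all transcripts
have an A as their first posttranscriptional nucleotide (the A-rich tail
regime). The same library under the `toe1_plus` preset gives ~63% mature
and ~0.17 mean A.

The same workflow is available from the shell:

```bash
snrnatail simulate --preset toe1_minus --seed 1 --out reads.fastq
snrnatail run-all --config run.yaml
snrnatail ddct --ct-table ct.tsv --controls 7SK,12S \
    --condition treated --reference-condition reference
snrnatail halflife --decay-table decay.tsv
```

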