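# Methods

## Coordinate system and gene models

All positions are relative to the mature 3′ end of the processed RNA:
position 0 is the last mature nucleotide, +k the k-th genome-encoded
nucleotide downstream of it, −k a terminus k nucleotides inside the mature
body. Intervals are closed on both ends. A gene model supplies the mature
sequence, the downstream genomic sequence (the template for extensions),
the 5′ anchor length used for gene assignment, and a category label.
Sequences are stored as RNA; DNA input is converted (T→U) with a logged
message, since reference files are typically DNA.

The downstream sequence length is the hard cap on callable templated
extension. A call whose templated end reaches that cap carries the
`hit_reference_cap` flag whether or not a tail follows, because in either
case the split is censored by the reference rather than decided by the
data: supply longer downstream sequence to resolve such calls.

## Read model and processing

Reads are single-end amplicons with fixed layout
`[insert][UMI][barcode][constant adapter]`, the insert running from the
gene-specific anchor through the 3′ terminus. The constant region is
located by its rightmost occurrence with ≤ 1 mismatch (rightmost, because
the insert may contain adapter-like subsequence; a match truncated by the
read end is accepted at ≥ 8 nt overlap). UMI and barcode are sliced at
fixed offsets; barcodes match a known set with ≤ 1 mismatch, requiring a
unique best hit. Failures are rejections with reason codes (`no_adapter`,
`bad_barcode`, `short_insert`, `no_gene`, `ambiguous_gene`), which are
mutually exclusive, exhaustive, and counted — never exceptions.

Gene assignment takes the registry gene whose anchor has the minimal
Hamming distance to the insert prefix, requiring a unique minimum ≤ 1
(configurable). PCR duplicates are collapsed by *exact* identity of
(gene, barcode, UMI, insert) — no directional UMI clustering. With a
substitution-only error model and short targeted amplicons, clustering
adds failure modes for little gain; exact collapse slightly over-counts
molecules under sequencing error, the conservative direction. The insert
is part of the key because targeted amplicons occupy a small sequence
space per gene, making (UMI, insert) far more collision-resistant than the
UMI alone. At very high per-gene depth (tens of thousands of molecules
sharing one insert) occasional residual (UMI, insert) collisions merge
truly distinct molecules; at 17,000 molecules per gene this affects ≈ 0.1%
of molecules and is accounted for in the recovery tests. Deduplication can
be disabled (`dedup: false`) to reproduce read-weighted conventions.

## End calling

`call_end` aligns the insert to the mature body (substitutions only, ≤ 2
mismatches by default; no indels — amplicons are short and anchored, and
excluding indels keeps the exhaustive oracle exact), then extends the
templated match greedily into the downstream sequence with zero mismatches
allowed in the extension, and reports the unmatched suffix as the
untemplated tail. If the insert ends inside the mature body the templated
end is the position of its last base and the tail is empty — the caller
cannot, by construction, distinguish a tail appended to a truncated end
from body mismatches, so the simulator does not generate that configuration
by default (`tail_on_truncated=False`).

The maximal-templated rule makes the split unique and deterministic. Its
one bias is explicit: a tail whose first base equals the next genomic base
is partially absorbed into the templated extension, so called tail length
≤ true tail length, with equality whenever the first tail base differs
from the next genomic base. `call_end_exhaustive` enumerates every
consistent split and returns the maximal-templated one; property tests
assert it equals the greedy caller on arbitrary inputs. A terminal
sequencing error can truncate the templated match and seed a spurious
1-nt tail; this is quantified under simulation rather than patched
heuristically (a `min_tail_report` style filter can be applied downstream;
all tails are reported by default).

## Statistics

One filtering rule everywhere: only transcripts whose apparent (actual)
end is at or downstream of the window start (−5 nt by default) enter the
distributions, percentages and tail statistics, and the excluded count is
always reported. Boundary classes are defined exactly: *mature* = apparent
end exactly 0 (no extension, no tail); *extended* = apparent end ≥ +1, so
a mature-positioned end carrying a tail counts as extended; *truncated* =
apparent end < 0. The three classes partition the in-window set.

The tail-composition matrix entry (i, b) is the % of in-window transcripts
whose tail is ≥ i nt long with base b at position i (i = 1..8 by default),
so row sums form the survival function "% with ≥ i added nucleotides" and
are nonincreasing. The denominator is all in-window transcripts by
default; a tailed-only denominator is available behind a flag. Mean A and
mean U per transcript count the base anywhere in the tail, with tailless
transcripts contributing 0, over the same filtered set.

Statistics are weighted per UMI-collapsed molecule by default; per-read
weighting is available, and the two coincide exactly when every molecule
has one read. Replicates aggregate as arithmetic mean ± SEM (sd/√n,
ddof = 1; flagged undefined for n = 1).

## Quantification

ΔΔCt: ΔCt = mean Ct(target) − mean over controls of mean Ct(control),
ΔΔCt = ΔCt(condition) − ΔCt(reference), relative level = 2^−ΔΔCt.
Controls average on the Ct scale (geometric mean of abundances), the
standard convention; the abundance-scale arithmetic mean is behind a flag.
Per-replicate levels pair each condition replicate against the reference
mean ΔCt to give an SEM. Amplification efficiency is assumed 2.0; no
multiple-testing correction is applied (per-comparison significance tiers
* p < 0.1, ** p < 0.05, *** p < 0.01 only).

Decay normalization divides the target level by the mean of stable control
levels at each timepoint and rescales to the 0-min ratio, so any global
multiplicative effect cancels. Half-lives come from OLS of ln(fraction) on
time with free intercept, t₁/₂ = ln 2/(−slope), R² reported; slope ≥ 0 is
reported as an infinite half-life with a `no_decay` flag. OLS with a free
intercept was chosen over a through-1 constrained or nonlinear fit because
it is closed-form, transparent, and exact on noiseless exponentials; it
requires ≥ 3 distinct timepoints, matching the 0/10/20/30-min shut-off
design. The t-test is the classical equal-variance two-sample Student's
test (Welch behind an option; a log2 mode for relative levels is exposed).

## Synthetic-data generator

The generator emulates the library chemistry, not the biology upstream of
it: metabolic labeling, pulldown efficiency and cross-linking are outside
the model ("nascent" is a sample label), and sequencing errors are
substitution-only (no indels). Each molecule draws a genome-encoded end
from a categorical distribution over [−5, +K], optionally a tail
(probability `tail_prob`, truncated-geometric length, per-position base
composition), and a duplicate count; reads get a fresh UMI per molecule, a
fixed per-sample barcode, the constant adapter, 'A' fill to the configured
read length, and per-base substitution errors. The adapter-internal layout
(UMI before barcode before constant region) is a package convention,
configurable, and self-consistent between generator and parser. All
randomness comes from one explicit seed per call; output is byte-identical
across runs.

Defaults: 10,000 molecules per gene, geometric duplication with mean 3,
read length 150, UMI length 10, constant Phred quality. Per-gene depths
and duplication rates of real libraries are not published for this assay
type; these are round numbers typical of targeted amplicon runs, not
calibrated values. The three condition presets encode the qualitative
regimes the assay distinguishes — deadenylase present (70% mature ends,
10% tail probability, A-rich tails), deadenylase depleted (ends shifted
into the extension region, 50% tailed, 85% A composition), and unstable
variant snRNAs (15% mature, 60% tailed, mixed 45/45 A/U tails) — with
5,000 molecules per gene. Directions of the preset contrasts are
guaranteed by construction; tests verify the pipeline reproduces them,
which validates the measurement chain, not the biology.

Decay curves are exponential with multiplicative lognormal noise of given
CV (the natural error model for abundance ratios); Ct tables invert the
ΔΔCt model, Ct = base_ct − log₂(abundance) + Gaussian noise (the natural
model on the cycle scale), so noiseless tables are recovered exactly by
the analysis.

## Problem sizes and tolerances

Recovery tests use an error-free 51,000-molecule library over downstream
sequences restricted to C/G so that A/U tails are never ambiguous; at this
n every percentage statistic is compared within ±1 absolute point (> 4
binomial standard errors) and mean A/U within ±0.05. The oracle-agreement
check runs 1,000 randomized gene/molecule pairs, half with A-rich
downstream context. Half-life recovery uses 100 replicates at CV 0.1 and
asserts the median within 10%; type-I calibration uses 10,000 null trials
at n = 5 per group against the [0.04, 0.06] band. Preset contrasts run at
1,500 molecules per gene. These sizes make the whole suite and the
acceptance script each complete in about a minute on one core.

## Known limitations

- The greedy split systematically undercounts tails over matching genomic
  context; no probabilistic deconvolution of this ambiguity is attempted.
- Exact-match UMI collapse over-splits molecules under sequencing error
  and can merge distinct molecules at extreme per-insert depth.
- No quality-aware trimming, paired-end support, or genome-wide alignment;
  gene models are supplied explicitly.
- Tails on truncated (< 0) ends are not representable by the caller.
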