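# Methods

## Scope and model

`zratio` implements a stratified differential-expression and gene-dosage
workflow for two-group microarray studies, motivated by trisomy-21
(Down Syndrome, DS) brain expression data. The pipeline consumes
already-normalized log2 probe intensities (RMA-style background
correction and normalization are upstream concerns and out of scope) and
produces, per gene and per stratum:

* a **Z-ratio** differential-expression score with a two-tailed normal
  p-value and an overexpression flag,
* a **dosage score**: the log2 fold difference M, the fold ratio
  R = 2^M, and a copy-number-style category.

A *stratum* is the whole brain, one of 11 region codes (HIP, CBC, DFC,
OFC, VFC, MFC, S1C, IPC, V1C, STC, ITC), or one of six age ranks
(16–22 weeks of gestation, 0–12 months, 2–10, 12–22, 30–39, 40–42
years). Every stratum is analyzed independently; a stratum missing
either group is skipped with a logged warning, never imputed.

## Per-sample Z-score

Each sample (array) column is standardized across its genes:

    z_gs = (x_gs − mean_g x_gs) / sd_g x_gs

The standardization runs over genes within a sample, not over samples
within a gene: it removes array-level location and scale effects, so
downstream statistics are invariant to adding a constant to a sample's
log2 values or rescaling them by a positive factor. The sample
(n−1-denominator) standard deviation is the default; a population
convention is available (`sd_convention="population"`). A zero
within-sample standard deviation is an error naming the sample — it
indicates a degenerate (constant) array.

Optionally Z-scores are winsorized to [−3, +3] after standardization
("clipping"). Clipping bounds the influence of extreme probes at the
cost of slightly perturbing the mean-zero/unit-variance property; it is
off by default and on in the replication profile
(`RunConfig.with_profile("paper")`). Clipping is applied before the
Z-ratio is computed; whether such bounding should precede or follow the
ratio is a genuinely open design point, so the flag lives in the config
rather than being hard-wired.

## Z-ratio

For one stratum with DS and control groups, per gene g:

    diff_g    = mean_s z_gs (DS) − mean_s z_gs (control)
    Z-ratio_g = diff_g / sd_g'(diff_g')

The denominator is the sample standard deviation of the differences over
**all genes analyzed in the stratum** — the full presence-filtered gene
universe by default. Restricting the universe to a short gene list
(`universe="listed_genes"`) is supported but discouraged for small
lists: with a handful of genes the denominator is an unstable estimate
and the scores become strongly interdependent. Per-sample
standardization always uses the full filtered matrix regardless of the
universe choice, since it is a per-array operation.

A gene is flagged **overexpressed** when its Z-ratio is strictly greater
than 1.96, the two-tailed 5% critical value of the standard normal
distribution; a value of exactly 1.96 is not flagged. Two-tailed
p-values are 2·(1 − Φ(|Z-ratio|)). Note the Z-ratio's null distribution
is not exactly standard normal — the denominator is estimated from the
same differences and the scores are normalized to unit sample variance
by construction — so the p-values are approximate and the flag should be
read as a conventional threshold, not a calibrated test. The test suite
pins the empirical null call rate as a frozen regression value rather
than asserting 2.5%. A Benjamini–Hochberg q-value column is emitted for
rigor but never gates the flag; no multiple-testing correction is
applied to the flag itself.

Antisymmetry (swapping the group labels negates every Z-ratio exactly)
and invertibility (Z-ratio × sd-of-diffs recovers the diffs) are tested
properties.

## Dosage score

M is computed on raw (unstandardized) log2 intensities — only there does
R = 2^M have fold-change meaning:

    M = mean log2(DS) − mean log2(control),   R = 2^M

R is read on a copy-dosage scale (a third copy of a disomic gene gives
R = 3/2). Categories, with all boundaries closed as stated:

| R | category |
|---|----------|
| < 0.80 | reduced |
| 0.80 – 1.30 | balanced |
| (1.30, 1.4) | gap_low |
| 1.4 – 1.7 | triplicated |
| (1.7, 1.8] | gap_high |
| > 1.8 | amplified |

The regions between the named bins are reported explicitly as
`gap_low`/`gap_high` instead of being snapped to a neighboring call: a
copy-number-style label should never be invented for a ratio the bin
definitions do not cover. Bin edges are configurable (`DosageBins`).

A consequence worth knowing: under the recovery conditions exercised in
the acceptance tests (planted 1.5-fold, 20 samples per group, residual
sd 0.2 log2 units), the sampling standard deviation of M̂ is
0.2·√(2/20) ≈ 0.063, so roughly 6% of replicates land in `gap_low`
(below R = 1.4) rather than `triplicated`. The strict-gap classifier
trades a few percentage points of labelled-triplicated sensitivity for
never fabricating a call; the corresponding acceptance test documents
the measured rate.

## Presence filter and stratification

The presence filter keeps a probe when its **linear-scale** intensity is
strictly greater than 100 in at least half the samples ("at least half"
is a plain ≥, so exactly n/2 qualifies on even n; an intensity of
exactly 100 does not). Log2 input is converted as 2^x first. The filter
is idempotent and is a no-op on data already filtered upstream.
Threshold and fraction are configurable.

Age ranks are closed intervals with a unit (WG/M/Y). Prenatal (WG) ages
only match WG bins; months ≥ 24 are converted to years and years < 2 to
months, so infant and adult ages land in the unit of their bin. Ages in
the gaps between bins (e.g. 25 Y) are left **unassigned** with a logged
warning — the bins are disjoint by design and nearest-bin snapping would
silently move samples across cohorts. Overlapping bin definitions are a
configuration error.

## Probe → gene collapse

When several probes map to one gene, per-sample values are combined by
the mean (default; symmetric and conventional for summarized microarray
data), median, or max. The collapse rule is configurable because no
single convention is canonical. Probes without a mapping are dropped
with a logged count; a single-probe gene passes through unchanged under
any rule.

## Network topology summaries

`netstats` computes, on a user-supplied interaction edge list: node,
edge, and connected-component counts, the number of multi-edge node
pairs, the average number of **distinct** neighbors (multi-edges
collapse, matching the NetworkAnalyzer/Cytoscape convention), and the
degree heterogeneity sqrt(population variance of neighbor count)/mean.
No interaction databases are queried; reproducing any particular
database export is out of scope because such networks depend on the
database version at query time.

## Synthetic data generator

`simulate_dataset` draws log2 values as

    x_gs = mu_g + delta_gs + e_gs
    mu_g ~ N(baseline_mean, gene_sd),  e_gs ~ N(0, noise_sd)

with `delta_gs = log2(fold_change)` exactly when sample s is DS and one
of the effect's strata (region code, age-rank label, or `Brain`)
contains s. Defaults emulate a stratified brain study: 17 000 genes, all
11 regions with 5 DS and 5 control samples each (≈55 per group overall),
ages uniform over the six ranks, baseline 8.0 log2 units, between-gene
sd 1.5, residual noise 0.2. One seed drives gene means, sample
assignments and noise, so outputs (including fixture files) are
byte-reproducible.

What the generator does **not** model: probe-level cross-hybridization,
intensity-dependent variance, batch effects, correlated co-expression
structure, or sex-chromosome dosage. Passing recovery tests therefore
demonstrates that the statistics recover planted effects under the
model's own assumptions (independent Gaussian log2 noise), not that they
are robust to real-array artifacts.

Test problem sizes are deliberately small where the quantity under test
allows it: parameter-recovery replicates use 10 genes (M depends only on
the planted gene's rows), the null-rate regression uses 200 replicates
of 500 genes, and the stratum-specificity vote uses 101 replicates of a
two-region design — a strict-majority design with an odd replicate
count.

## Numerical and interface choices

* Standardization invariants are asserted to 1e-9; R = 2^M to 1e-12
  relative; round-trip file I/O to 1e-5 (values are written with 10
  significant digits).
* Report TSVs display Z-ratios rounded to two decimals with an `*` on
  flagged cells; flags are always computed at full precision so display
  rounding can never move a call.
* The whole-brain column pools all samples by default; an alternative
  that averages per-region Z-ratios is available
  (`brain_pooling="mean_of_regions"`) since either pooling is defensible.
* Degenerate inputs fail loudly and specifically: empty matrices, zero
  within-sample variance, identical DS/control groups (zero SD of
  differences), unmapped report genes, malformed edge-list rows (with
  line numbers).
* The series-matrix reader extracts metadata from free-text
  characteristics lines via configurable regex patterns; unknown regions
  and sexes fall back to an explicit `unknown` sentinel rather than
  guessing.

## Known limitations

* P-values inherit the normal approximation discussed above; no
  moderated-variance (limma-style) inference is offered.
* The presence filter assumes the >100 threshold is meaningful on the
  input's linear scale; data summarized on other scales need a custom
  threshold.
* Gene-level collapse assumes each retained probe maps to at most one
  gene; cross-mapping probes must be resolved in the annotation.
* The CLI covers the standard flows; unusual configurations (custom age
  bins, population-sd convention, alternative dosage bins) are reached
  through `RunConfig` / the YAML config file.
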