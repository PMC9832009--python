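# Methods

## Problem setting

A replicated time-course expression experiment watches a tissue approach
and cross an abrupt state transition — here the adeno-to-squamous
transdifferentiation (AST) of *Kras*/*Lkb1*-mutant lung tumors, sampled at
0/4/6/7/8/9/10 weeks after tumor induction. Dynamic network biomarker
(DNB) theory predicts that just before the transition a subset of genes
starts fluctuating collectively: within-group correlation and variance
rise while correlation to the rest of the transcriptome falls. `dnbtrack`
operationalizes this as a per-timepoint composite index and locates the
tipping point at its maximum.

## Normalization

Counts are normalized with relative log expression (RLE, median of
ratios): per-sample factors are the median over genes (restricted to genes
with nonzero counts in every sample) of the ratio of the sample's
library-size-normalized proportion to the per-gene geometric-mean
proportion, rescaled to geometric mean 1. The effective library size is
`library_size x factor`, and expression values are
`log2(1e6 * count / effective_library_size + 1)`. The +1 pseudocount on the
RPM scale keeps zeros at zero; it is configurable. Computing factors on
proportions (rather than raw counts) makes normalized values exactly
invariant to rescaling any single sample's counts, which is the behavior
the factor-based convention is chosen for.

## The composite criticality index

For a candidate module *M* inside a candidate gene subspace *S* at one
time point with replicate samples:

- `PCC_i` — mean of |Pearson r| over unordered pairs within *M*;
- `PCC_o` — mean of |Pearson r| over pairs (*M* x *S*\*M*);
- `SD_i` — mean over genes in *M* of the replicate standard deviation
  (ddof = 1) of normalized log2 expression;
- `CI = (PCC_i / max(PCC_o, 1e-6)) * SD_i`.

The epsilon floor only guards the degenerate all-orthogonal case. `SD_i`
is the raw within-timepoint SD by default; a `sd_relative_to_baseline`
variant (dividing by the module's mean SD across time points) can be
obtained by post-processing the per-timepoint profile, but raw SD is the
tested default. Correlations are computed across replicates only; at least
3 replicates are required, otherwise the scan refuses and points to the
sliding-window variant.

Candidate modules are enumerated deterministically: average-linkage
hierarchical clustering on distance 1 − |r|, where every internal node of
the dendrogram whose size lies in [5, 200] is a candidate (equivalently:
cut the tree at every merge height and keep every resulting cluster once).
Candidates are ordered by decreasing mean within-cluster |r| with
lexicographic tie-breaks, CI is evaluated for every candidate, and the
max-CI candidate is the dominant group of the time point. The tipping
point is the argmax over time of the dominant CI, ties resolved toward the
earliest time point (the conservative, earliest-warning call). Everything
is deterministic: two runs on the same input produce identical profiles.

### The candidate subspace

The scan is meant to run inside a lineage-differential candidate subspace,
estimated on an independent two-lineage cohort (in the motivating study: a
large external ADC-vs-SCC tumor compendium). `signatures.lineage_subspace`
derives it with the package's differential test at fold change > 2 and
BH-adjusted P < 0.001. When no subspace is given, `dnb_scan` falls back to
the top 2000 most-variable genes. The subspace matters: with 6 replicates
the null distribution of |r| is wide (E|r| ≈ 0.36, P(|r| > 0.8) ≈ 5.6%),
so in an unconstrained 600-gene space dozens of background genes are
statistically indistinguishable from module members at a single time
point. Constraining the scan to the differential program removes most of
that background and is what makes module-membership recovery meaningful.

### Resolution limits worth knowing

- **Tipping-point location** is recovered robustly (~95% of simulated
  default-condition series); the ~5% failures are series in which the six
  sampled replicates happen to under-express the critical fluctuation (low
  sample variance of the shared module factor) — a real property of
  small-replicate designs, not of the estimator.
- **Module membership** is noise-limited: at 6 replicates the CI
  difference between the planted module and its nested sub-blocks or
  slightly contaminated superblocks (5–20%) is comparable to correlation
  sampling noise, so the dominant module is essentially composed of
  planted genes (precision ≈ 0.9–1.0) but its exact boundary wobbles;
  Jaccard overlap with the planted module is ~0.8 in the median and
  exceeds 0.8 in only ~55–70% of series. Reliable exact membership would
  need roughly twice the replication.
- **Sliding-window scans** label each pooled window by its central time
  point and localize the transition to window resolution. With the
  critical spike confined to one time point and equal replicate counts,
  the length-3 windows containing the tipping point are statistically
  exchangeable up to the (weak) asymmetry contributed by switching gene
  means, so the recovered label is guaranteed to be a window *containing*
  the tipping point (~90–95% of series) but not reliably the exact central
  week.

## PCA trajectory and dispersion

Samples are embedded on the first two principal components of the
gene-centered matrix (no unit-variance scaling by default, preserving
high-variance markers; scaling is a flag). Sign convention: each loading
vector is flipped so its largest-magnitude entry is positive, making
embeddings reproducible. Per-timepoint dispersion is the mean Euclidean
distance of a time point's samples to their centroid in the 2-D embedding
(mirroring the visual argument that pre-transition samples scatter more);
singleton time points are reported missing.

## Signatures, differential sets, AST score

Pathway/TF-target signatures use the combined-z method: member genes are
z-standardized across the cohort (zero-variance genes contribute 0) and
per-sample scores are `sum(z) / sqrt(k)`. Lineage component scores are
plain means of z-values over the genes upregulated in ADC (or SCC), and
the AST score is their difference (SCC − ADC), so exchanging the two sets
negates it exactly. The standardization universe is the cohort passed in.

Differential gene sets come from a per-gene Welch t-test on normalized
log2 values with BH adjustment and a fold-change gate (defaults: fold
change > 2, adjusted P < 0.001). This is a deliberately simple, pluggable
stage — callers with count-model differential results (e.g. from a
quasi-likelihood framework) can inject their own gene sets everywhere a
`GeneSet` is accepted.

## Mutual-suppression network

`overlap_test` computes the one-sided hypergeometric enrichment tail
P(X ≥ overlap) (a two-sided Fisher variant is available), with odds ratios
from the 2×2 table (0.5 continuity correction only when a margin cell is
zero, flagged). The gene universe is always explicit because it dominates
the p-values; the recommended default is all genes present in the
expression matrix. `build_yinyang_network` pools each TF family's targets,
tests ADC-family targets against the transition-repressed set and
SCC-family targets against the transition-induced set, BH-adjusts the two
family tests, and declares mutual suppression only when both pass alpha
(default 0.05). Requiring both directions keeps the null verdict rate well
below alpha (≈0.5% measured on random target families). Per-TF edges
weighted by odds ratio are emitted for reporting.

## Synthetic data generator

`generate_timecourse` emulates the study conditions: 7 time points, 6
replicates each, 600 genes of which 30 form the DNB module and 20 + 20 are
ADC/SCC markers. Per time point and replicate, gene-level log2 deviations
follow a factor model `x = sqrt(rho_x) F + m(t) M + e` with a background
factor F shared by all non-marker genes (`rho_x = 0.1`) and a module
factor M giving within-module correlation `rho_base = 0.2` away from the
transition. At the tipping point (7 weeks) the module's correlation jumps
to `rho_peak = 0.85`, its loading on F is zeroed (the outside-correlation
drop), and its latent SD is multiplied by `sd_inflation = 3`. Markers
switch sigmoidally (magnitude 3 log2 units, steepness 0.5 weeks, matching
a transition that completes between 6 and 8 weeks); module genes carry the
same coherent switch because the DNB emerges inside the lineage-
differential program. Latent means are emitted as negative-binomial counts
(gamma–Poisson, dispersion 0.1) around per-gene base levels drawn
log-uniformly over log2 counts 5–10 (the expressed-gene range). The latent
SD (1.0 log2 unit, i.e. 2-fold typical inter-animal variation) is chosen
so that count-level noise attenuates the planted correlation by < 20%,
keeping the configured rho values interpretable as observed module
correlation. All draws derive from a single seed; identical configs are
bit-reproducible.

`generate_adsc_cohort` mixes the ADC and SCC marker/module programs per
sample with a convex mixture fraction f (plus Gaussian noise, SD 0.5), and
plants a "Wnt-like" gene set that decays linearly with f (2 log2 units),
mimicking Wnt signaling being shut off as tumors become squamous.

What the generator does *not* model: batch effects, library-size outliers,
gene-length bias, compositional effects, single-cell structure, or
transitions spread across multiple time points. Passing tests on this
generator therefore demonstrate correctness of the estimators under the
planted model, not robustness to those real-data complications.

## Problem sizes used in validation

Validation simulations use the default conditions above: 20-series
ensembles for recovery statistics in the test suite (40 in the acceptance
script, where the modal recovered week is also reported), 50-sample
cohorts for AST mixture recovery, and 200 simulated datasets for each null
calibration (differential test at 200 genes × 6 vs 6 samples; mutual-
suppression verdict with two 2-TF families of 100 random targets in a
2000-gene universe). These sizes give binomial standard errors of a few
percent on the reported rates while keeping a full validation run in
seconds on one CPU.

## Cohort incidence

Incidence percentages are `100 * n_with_scc / n_total` rounded half-up to
whole percent (matching how such figures are conventionally printed), with
the exact fraction always reported alongside; empty groups yield missing
values.
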