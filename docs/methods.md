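# Methods

## Problem setting

Given a log2-scale gene × sample expression matrix and a binary outcome per
sample (survivor / non-survivor), the pipeline asks whether a small gene
signature — genes tied to a biological process, filtered for association
with outcome — carries prognostic information, and whether that information
exceeds what arbitrary gene sets of the same size provide.

## Differential expression and filtering

Group contrasts are two-sided t tests on log2 values, Welch by default
(`equal_var=True` gives the Student variant). The effect size is the
difference of class means on the log2 scale (alternative − reference:
non-survivor − survivor, or perturbed − control). FDR is Benjamini–Hochberg
across all genes in the matrix, per contrast. A gene is a DEG when its
linear fold change `2^|log2fc|` strictly exceeds 1.5 **and** its FDR is
strictly below 0.05, in either direction. Genes with zero variance in both
classes get p = 1 (not NaN) so downstream set algebra stays total.

The original DE test behind the published gene lists is not recorded;
Welch is the least-assumption default for two-group comparisons of
normalized array data, and no attempt is made to reproduce exact published
DEG counts from raw data.

## Signature construction and weights

The signature is the intersection of a process-associated gene set with the
survival DEGs, ordered alphabetically for reproducible serialization. The
per-gene weight definition in the source analysis is underdetermined, so
three conventions are implemented and recorded in output metadata:

* `sign` (default): W = +1 for genes down in non-survivors, −1 for genes up.
  This is the weakest assumption that makes lower scores mark worse
  prognosis, which is the orientation the score is used with.
* `log2fc`: W = −log2fc — same orientation, magnitude-weighted.
* `unit`: W = 1 (orientation-blind; useful for nulls and ablations).

## Survival score and risk groups

score(s) = Σ W_i (e_is − μ_i)/S_i, with μ_i and S_i computed over **all**
samples of the dataset being scored (classes pooled), S with the n−1
denominator. Each cohort is standardized against itself by default —
validation cohorts are scored independently of discovery — but discovery
stats can be frozen and applied externally for deployment-style scoring.
Scores are invariant to per-gene positive affine transforms of the input
when stats are recomputed, so unit/offset differences between platforms do
not matter by construction.

Risk groups split at the mean score by default; the source description uses
"mean" in its methods but "medium" (median) in its results, an inconsistency
resolved by making the rule explicit (`mean`/`median`) and logged. Ties at
the threshold go to the low-score group, so "above the mean" is strict.
Missing or zero-variance signature genes are dropped with a warning rather
than imputed.

## ROC, AUC, and the AUC-sum composite

AUC is the rank statistic (normalized Mann–Whitney U): the probability that
a random positive sample outscores a random negative one, ties counted ½.
The positive class defaults to "survivor" with higher score ⇒ survivor. The
ROC curve is the exact step curve over distinct thresholds; its trapezoidal
area equals the rank AUC (asserted exactly in tests, including heavy ties).
Cross-cohort performance is summarized by the arithmetic sum of per-cohort
AUCs (range [0, #cohorts]; 1.0 is chance for two cohorts).

## Random-signature empirical null

To judge a k-gene signature, random k-subsets are drawn uniformly without
replacement from a gene universe (whole genome, or a restricted list),
**re-weighted from the discovery contrast exactly as the observed signature
was** — a fair null requires random sets to enjoy the same orientation
advantage — scored on every cohort, and reduced to the AUC sum. Per-cohort
AUC draws are also emitted, since a density over single-cohort AUCs is an
equally valid reading of the composite display. The one-sided empirical p
uses the add-one rule p = (1 + #{draws ≥ observed})/(n_draws + 1), which is
never zero and is uniform under the null (verified by calibration
simulation). The universe is restricted to genes measured with non-zero
variance in every cohort.

## Enrichment score

Genes are ranked by a class-contrast metric (signal-to-noise
(μ_A − μ_B)/(σ_A + σ_B) by default, A = reference class; t statistic and
log2fc available), descending, alphabetical tie-break. The running sum
increments by |metric|^p (normalized over set members) at members and
decrements by 1/(N − N_hit) elsewhere; ES is the signed extremum. At
exponent 0 this is exactly the signed Kolmogorov–Smirnov statistic between
member and non-member rank positions (asserted against a direct ECDF
computation). Significance is by phenotype permutation: NES = ES divided by
the mean |ES| of same-sign permutations; p is the add-one same-sign tail
fraction; FDR across sets is BH on those p-values — a deliberate
simplification of the classic NES-binned FDR estimator, chosen because only
a single FDR cutoff (0.25) is consumed downstream. Sample-level variance
estimation (GSVA-style) is intentionally out of scope.

## Synthetic cohorts

`simulate_cohort` draws i.i.d. normal log2 noise (default SD 1.0) around
per-gene baselines (~N(8, 1.5), typical log2 microarray intensity), adds an
additive shift of `effect_size` (default 1.0 SD, sign configurable per gene,
default up in non-survivors) to planted genes in the non-survivor arm, and
optionally correlates planted genes through a single shared latent factor
(pairwise correlation exactly `block_correlation`; default 0.0 — correlation
is an explicit opt-in, not part of the default world). Default cohort sizes
are 187 survivors / 78 non-survivors, the discovery-cohort geometry the
pipeline is validated against; the validation geometry is 50/56.
`simulate_perturbation` is the two-arm analogue with planted signed log2
fold changes and classes (control, perturbed). Outcomes are assigned by
design (fixed arm sizes): the analysis conditions on labels, so no
risk-generating model is simulated.

The simulator deliberately omits batch effects, probe saturation,
heteroscedastic intensity-dependent noise, and survival times. A green test
on synthetic data therefore establishes correctness of the statistical
machinery under the stated model — normal noise, additive effects, fixed
arms — not robustness to real microarray artifacts.

## Numerical conventions

* Sample SD uses the n−1 denominator everywhere.
* Thresholds: fold change and FDR cuts are strict inequalities, as is the
  interaction-score cutoff (> 0.7) and "above the mean" classification.
* AUC ties get half-credit; ROC trapezoids make the areas agree exactly.
* PCA components are sign-canonicalized (largest-magnitude loading
  positive); variance explained is reported per component and combined.
* Expression TSV round-trips are bit-exact (`%.17g` on write, `float()`
  parsing on read).
* Permutation and resampling p-values use the add-one rule.

## Limitations

* The fixture source lists are synthetic stand-ins constructed to reproduce
  the published signature memberships; only those memberships are real.
* Weight conventions other than ±1 are speculative; results with
  `log2fc` weights should be interpreted as a sensitivity analysis.
* No confidence intervals on AUC (DeLong) and no Cox/survival-time
  modelling — the outcome is strictly binary.
* Immune-cell deconvolution and pathway-database retrieval are out of
  scope; enrichment is exercised on synthetic and fixture gene sets only.
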