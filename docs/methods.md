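# Methods

This note documents the generative model behind the synthetic cohort,
the statistical procedures of the four pipeline steps, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The synthetic cohort

The generator emulates a small two-group cirrhosis cohort: `n_case = 6`
patients with minimal hepatic encephalopathy (MHE) and `n_control = 5`
without, profiled on three layers — a blood gene-expression array
(default 5,000 genes; a full-scale configuration mirrors an 8×60K array
with 60,000), a 143-metabolite targeted serum panel with the class
composition 8 acylcarnitines / 21 amino acids / 17 biogenic amines / 1
hexose sum / 15 sphingomyelins / 81 glycerophospholipids, and a
14-cytokine ELISA panel. All matrices are written on the measurement
scale (intensity, µM, pg/ml = `2^log2value`); the analysis re-derives the
log scale through its own variance stabilization.

### Genes

Per-gene log2 baselines are uniform on (6, 14). Residual variances are
drawn from a scaled-inverse-chi-square prior `s² ~ d0·s0²/χ²_{d0}` with
default `(d0, s0²) = (4, 0.05)` — the same working model the
empirical-Bayes moderated t assumes, which makes hyperparameter recovery
a fair test. 847 genes carry planted case-vs-control log2 fold changes
with magnitudes uniform on (0.8, 2.0) and random sign.

### Latent modules

Six latent modules tie the serum compounds together. Module *m* has a
factor

```
f_ms = shift_m · 1[case_s] + u_ms ,   u_ms ~ N(0, 1)
```

and a member compound *i* is generated as

```
x_is = baseline_i + sign_i · λ_i · f_ms + ε_is .
```

Member loadings are derived from the planted log2 fold changes:
`sign_i = sign(logFC_i)` and `λ_i = |logFC_i| / shift_m`, so the group
effect of a member (`sign·λ·shift = logFC`) and its co-variation with the
rest of the module arise from a single mechanism. The within-group
component `u` is **centered per group**, so the realized fold change of
every member equals its planted value exactly instead of being perturbed
by one shared factor draw — without this, an unlucky factor draw shifts
an entire module's observed effects at once and parameter-recovery tests
measure factor luck rather than pipeline behavior.

Default modules: the six differential cytokines form one module; the
significant phosphatidylcholines/lysoPCs split into three modules by
side-chain mass and saturation (more than 40 carbons; at most 40 carbons
with more than 5 double bonds; at most 40 carbons with at most 5 double
bonds, divided into diacyl-PC versus acyl-alkyl-PC/lysoPC groups); the
remaining small molecules and sphingomyelins form the sixth. The
carbon/double-bond rules are stated study observations; the exact
member-by-member composition is an approximation chosen here, since only
module 1 is enumerated in the source study.

A subset of the planted genes (default 25 per module) is **coupled** to
each module's factor: `x_gs = baseline_g + κ_g·f_ms + ε_gs` with
`κ_g = logFC_g / shift_m`. Coupled genes therefore carry both a group
effect and the module's within-group variation — the signal the PLS step
is designed to recover. Ground truth (planted effects, module members
with signs and loadings, coupled genes) is written to `truth.json`.

**Background class coupling.** Real serum panels are correlated within
chemical classes whether or not a compound responds to disease. Every
non-planted feature therefore receives a weak loading (magnitude uniform
on (0.15, 0.30), random sign) on the *within-group component only* of
the module its chemistry matches (lipids by the carbon/double-bond
rules, other small molecules to the small-molecule module, non-planted
cytokines to the cytokine module). These features remain exact nulls for
the group contrast, but a chance FDR crossing then co-varies with its
class module and is absorbed by the clustering instead of distorting the
selected module count as a spurious singleton. The hexose sum stays
fully independent.

### Noise scales and power

Member noise is proportional to effect size (`ε` SD = 0.05·|logFC|),
and factor shifts are 2.5 (metabolite modules) and 3.5 (cytokine
module). These were fixed once from the power arithmetic a practitioner
would apply at n = 6/5: the implied within-group SD of ≈ 0.4·|logFC|
gives moderated-t statistics ≈ 4 for every planted metabolite — the
regime the study's printed FDR range (5·10⁻⁴ … 0.048) implies — and the
larger cytokine shift gives the near-complete group separation that
exact rank-sum tests at BH-FDR < 0.05 on a 14-feature panel require.
Null metabolite SDs are uniform on (0.10, 0.25) log2 units (biological
CVs of roughly 7–19 %, as for an absolutely quantified targeted panel).

### What the generator does not emulate

No missing values by default (the emulated panel is post-QC; the
`censor_below_lod` operation exists to exercise the QC rules), no batch
or array effects beyond a global affine distortion, Gaussian log-scale
noise only, exactly one factor per module, and no gene–gene co-expression
beyond the module couplings. Passing tests therefore demonstrate correct
recovery of planted low-rank + group-shift structure at the study's
sample size — not robustness to heavy-tailed noise, batch confounding, or
overlapping modules.

## Step 1: normalization and differential testing

`vst_normalize` is a deliberately simple deterministic variance
stabilization, not the full maximum-likelihood VSN: (1) optional
per-sample affine calibration — each sample is regressed on the
across-sample median reference with a Theil–Sen fit (exact for an affine
distortion; on matrices above 800 features the fit uses a deterministic
rank-spread subsample of 800 features to avoid the quadratic pairwise
cost); (2) a global glog2 parameter `b` chosen by grid search (41
log-spaced candidates between the 0.1th and 99.9th percentile of the
calibrated values) minimizing the dimensionless slope of per-feature SD
against the rank of the feature mean. Calibration never sees group
labels.

The pipeline applies calibration to gene intensities but **skips it for
the metabolite panel** (`calibrate=False`): targeted metabolomics is
absolutely quantified against isotope-labeled internal standards, so
per-sample affine correction is unwarranted — and on a 143-feature panel
in which ~20 % of features shift coherently in one direction, any
per-sample location/scale fit leaks the group signal into the sample
factors and manufactures false positives among the nulls. This is a
known failure mode of reference-based normalization on small panels with
asymmetric signal, and it is documented here because the pipeline's
default depends on it.

The moderated t-test estimates `(d0, s0²)` by the method of moments on
`log s²_g` (digamma/trigamma moment matching; trigamma inverted by
Newton), caps `d0` at 10⁶ for numerical stability, and reduces exactly
to the ordinary two-sample t when `d0 = 0`. Per-sample weights default to
uniform (no weight source is defined for this design) with a hook for
user-supplied weights. Metabolite QC uses a strict `<` for the 20 %
missingness rule and an inclusive `≥` for the 50 %-above-LOD rule
("above" itself is strict), both configurable. Wilcoxon tests are exact
(full-distribution) for total n ≤ 20 without ties, normal-approximated
with tie correction otherwise; a Fligner–Killeen homoscedasticity p-value
is reported per feature but never gates the test, since no action on
failure is defined. BH adjustment propagates NaNs and excludes them from
the test count.

## Step 2: module discovery

Absolute Spearman correlations (average-rank ties; constant features set
to 0 with a warning) feed the distance `d = sqrt(2(1 − r²))` ∈ [0, √2].
PAM uses deterministic greedy BUILD initialization and best-improvement
SWAP (objective non-increasing; optional seeded random restarts, default
0). A medoid is always assigned to its own cluster so duplicate points
cannot empty one. K-means runs on a classical (Torgerson) MDS embedding
of the distance (up to min(n−1, 10) positive-eigenvalue dimensions) —
an approximation, since k-means needs coordinates; hierarchical
clustering is average-linkage on the distance directly. Selection
maximizes mean silhouette over methods × k ∈ 2..min(10, n−1); ties break
to smaller k, then PAM < k-means < hierarchical; a best mean silhouette
below 0.25 flags the partition as low-signal. Singleton clusters get
silhouette width 0. Clustering runs on the variance-stabilized scale
(rank-based correlation makes the choice nearly immaterial). Module
profiles z-score each feature, seed member orientation from the first
member (a module of perfectly anti-correlated halves would otherwise
average to zero), and flip anti-correlated members over two refinement
passes (a fixed point in practice).

## Step 3: PLS integration

NIPALS PLS2 with deterministic initialization (the response column of
maximal variance), convergence tolerance 1e-10 on the score vector, at
most 500 iterations, X- and Y-deflation per component. Both blocks are
autoscaled by default (centering-only available) because the responses
mix µM and pg/ml scales. A = 2 components by default; interpretation
uses component 1. R² is the cumulative fraction of (scaled) response
variance explained. Q² uses strict leave-one-out hygiene: every fold
re-estimates centering and scaling on its training samples, predictions
and totals are accumulated on the training-fold scaled space, and
`Q² = 1 − PRESS/TSS` with TSS against training-fold means; it is
reported cumulatively per component (the convention chosen here; a
per-component definition is not used). Gene rankings sort by
first-component X-weight, ties broken by gene id.

At n = 11 the leave-one-out Q² of a single model is a noisy statistic:
across seeds, per-module values at the default signal strength span
roughly 0.3–0.9 while their per-module medians are stable (≈ 0.65–0.8).
Summary claims about Q² are therefore made on per-module medians across
a seed suite, never on a single draw; single-model values are still
reported per run.

## Step 4: enrichment and networks

Over-representation uses the one-sided hypergeometric tail (the
"unusually many genes in the list" direction; a two-sided variant is
available by flag) with two flagged tiers, p < 0.05 primary and p < 0.1
relaxed — the relaxed tier mirrors the practice of manually including
near-threshold pathways and is never applied silently. Ranked enrichment
regresses set membership on the centered normal quantiles of the loading
rank (robust to the loading scale) by logistic regression with Wald
inference; on separation or unstable fits it falls back to the
always-defined Rao score test, flagged in the `method` column. BH across
sets is applied per module (a global variant is a flag). Term–term edges
use the Jaccard index of member sets (threshold 0.1, configurable) as a
transparent stand-in for curated pathway-relation databases, which are
out of scope. The term–module graph links a term to every module in
whose loading enrichment it is significant; degree ≥ 2 terms are flagged
central, the rest peripheral. Network writers sort nodes and edges
canonically, so outputs are byte-stable.

## Determinism and degenerate inputs

One integer seed drives every random draw through a single
`numpy.random.Generator` chain; identical configs produce byte-identical
output files. Degenerate inputs are handled explicitly: constant
matrices (warned, identity-like transform), constant features (zeroed
correlation), all-tied panels (p = 1 with warning), zero-variance
predictors (dropped under autoscaling), empty significant lists (the
pipeline stops gracefully after Step 2 and says why), modules without
compounds (skipped with warning).

## Known limitations

Single-factor modules and Gaussian noise understate the messiness of
real serum metabolomics; the gene expression layer has no correlation
structure beyond module couplings, making the PLS problem cleaner than
real transcriptomes; the silhouette-based k selection is sensitive to
isolated false-positive features when a panel lacks class correlation;
and at n = 11 every cross-validated quantity has a wide sampling
distribution — conclusions from any one synthetic cohort should be
treated exactly as cautiously as from the real one.
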