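# Methods

This note documents the models implemented in `fibroscope`, the defaults of
the synthetic study generator, the numerical choices, and the limits of what
the synthetic benchmarks demonstrate.

## The synthetic study generator

The generator (`fibroscope.syndata`) emulates a bulk + single-cell liver
fibrosis study so that every analysis stage can be exercised against known
ground truth. It is first-class, tested code, not a fixture dump. All
randomness flows from `StudyConfig.seed` through independent per-component
`numpy.random.Generator` streams, so regenerating any component is
byte-identical and components remain mutually consistent.

**Cohort.** 143 samples by default, distributed over normal histology and
NASH CRN fibrosis stages as 31 N / 35 F0 / 30 F1 / 27 F2 / 8 F3 / 12 F4,
with sex, age and batch covariates whose stage profiles resemble a bariatric-
surgery-dominated NAFLD cohort. Each sample carries a hidden
`latent_severity` = stage target (N = −1, F0..F4 = 0..4) + N(0, 0.15): the
within-stage continuum a continuous image score is meant to expose. It is
exported for testing only.

**Single-cell reference.** Four cell types (hepatocyte, cholangiocyte,
hepatic stellate cell, macrophage), 4 subjects, 400 cells per
(subject, type). Per-gene archetype means are lognormal; each type gets 20
marker genes whose archetype mean is 15× the maximum of the other types
(specificity floor 10×, so subject jitter cannot erode it below the floor).
Subject profiles are the archetype perturbed by lognormal jitter (σ = 0.25),
normalized to relative abundance and scaled to a per-type cell library size
(hepatocyte 1.5×, cholangiocyte 1.0×, HSC 0.8×, macrophage 1.2× of 2000
counts — hepatocytes are large transcript-rich cells, stellate cells small).
Counts are negative binomial with variance μ + φμ² (φ = `nb_dispersion`,
default 0.1), sampled gamma–Poisson. 400 cells per (subject, type) make a
400-cell flat-Dirichlet pseudo-bulk mixture always satisfiable without
replacement.

**Proportions.** Per-stage mean composition vectors are free parameters of
the generator (no public cohort publishes them); the defaults fall for
hepatocytes 0.70 → 0.35 from N to F4 and rise monotonically for
cholangiocytes (0.04 → 0.15), HSCs (0.10 → 0.24) and macrophages
(0.16 → 0.26), the qualitative pattern deconvolution studies of NASH livers
report. Sample compositions are Dirichlet around the stage mean with
concentration 200 (within-stage sd ≈ 0.03 for the hepatocyte fraction);
concentration ∞ returns the means exactly.

**Bulk mixtures.** Expected expression of gene g in sample i is

    libsize_i · norm( Σ_c p_ic · θ_gc · 2^(β_gc·d_i) · 2^(lfc_g·sev_i) )

where θ_gc are the reference's absolute per-cell mean counts (relative
profile × cell library size — this scale is what makes `p` a cell-count
fraction and lets the deconvolution's size-factor correction recover it),
d_i indicates advanced disease (F3/F4), and sev_i rescales latent severity
to [0, 1] so `lfc_g` reads as the log2 fold change between normal liver and
cirrhosis. By default 4% of genes (200 of 5000) carry a stage-monotone
effect of magnitude 1 (random sign) and a disjoint 2% carry a cell-type-
specific disease effect of magnitude 1 in one random type. Library sizes are
lognormal (σ = 0.3) around 10⁶. `nb_dispersion = 0` switches every count
generator to exact means — the deterministic mode the closed-form tests use.

**Tiles.** Each image receives a uniform 8–500 tiles (biopsy images range
from a handful to hundreds). Each of the eight morphometric features is an
affine function of latent severity plus N(0, `tile_noise_sd` = 0.3):
collagen-area features and void counts load positively, tissue/void
compactness negatively — fibrotic tissue is collagen-rich and porous.

Gene identifiers reserve the published 26-/98-gene signature names as a
prefix block so set-arithmetic fixtures can run against generated matrices.

## ImageScore

One repetition: down-sample every image to 6 tiles (images with fewer keep
all; the draw is made on a canonical within-image ordering so the result is
invariant to input row order), split *patients* into 20 CV folds, and per
fold: center/scale training tiles, fit PCA, keep the fewest components
reaching 90% variance (cap 8), represent each patient by the componentwise
median of their tiles' PC scores, fit an ε-insensitive RBF SVR (C = 1,
ε = 0.1, γ = 1/n_features) against the numeric stage targets, and predict
held-out patients. 100 repetitions by default; each sample's ImageScore is
the median of its per-repetition predictions, which bounds the influence of
any minority of aberrant repetitions by the perturbation size.

Folds split patients rather than tiles deliberately: tile-wise splitting
would place tiles of one patient on both sides of a fold and leak identity.
Stage targets N = −1, F0..F4 = 0..4 make the target affine in stage with
normal histology preceding F0. Tile clustering is k-means (k = 4,
k-means++ with 10 restarts, seeded) on standardized tile PC scores, with
per-sample cluster occupancy ratios reported against stage.

**Rank agreement reporting.** Results carry both Kendall τ-b and the
Goodman–Kruskal gamma. τ-b's denominator counts pairs tied in stage, so a
continuous score can never reach τ-b = 1 against a tied ordinal even when
every cross-stage pair is ordered correctly; gamma restricts to untied pairs
and equals 1 exactly in that case. On the default synthetic cohort the
noiseless-tile ImageScore reaches gamma = 1 while τ-b plateaus near 0.9 for
purely combinatorial reasons.

## Consistency-weighted deconvolution

`build_design` summarizes the reference per (subject, type) with ≥ 10 cells:
mean counts scaled to relative abundance, then cross-subject mean θ̄_gc and
variance v_gc (≥ 2 subjects required), cell-size factors S_c = mean library
size of the type's cells, genes with all-zero profiles dropped. No marker
pre-selection: all genes shared with the bulk matrix enter the solver.

`deconvolve` iterates, per sample, weighted NNLS on the library-size-
normalized bulk vector with weights w_g = 1/(ν + Σ_c q_c² v_gc), ν = 1e-8,
until the relative loading change falls below 1e-6 (max 100 iterations;
non-convergence is flagged, not raised). Proportions are size-corrected
renormalized loadings p_c = (q_c/S_c)/Σ(q/S). This is a concrete fixed
iteration honoring the published cross-subject-consistency weighting
principle — documented as MuSiC-style, not a clone. Uniform weights (v ≡ 0)
reduce it to plain NNLS; estimates are invariant to positive scaling of a
sample's counts.

The pseudo-bulk benchmark draws target compositions from a flat Dirichlet,
samples the implied cell numbers (largest-remainder rounding) without
replacement from one subject, sums counts, and records realized cell-count
fractions as truth. Recovery is summarized per type (Pearson r, RMSE) and
overall. Cell types whose estimated proportion stays below 5% at every stage
are flagged as high-variability and should not be interpreted.

## Cell-type-specific differential expression

Per gene, log2(TPM+1) is regressed on
[proportions | proportions × disease | covariates] with no intercept (the
proportion block sums to 1 and absorbs it). Disease is F3/F4, control F0/N;
samples at other stages are dropped; sex is the default covariate. A ridge
penalty (1e-6) on the interaction block stabilizes the near-collinear
design; with the penalty → 0 the estimator is exactly OLS. Wald t tests on
the interaction coefficients are BH-corrected across all (gene, type) tests
jointly. Effects read as cell-type-specific log2 fold changes.

A structural caveat verified by simulation: per-type interaction effects are
identifiable only when composition varies across samples. If proportions are
nearly constant within groups, the interaction columns collapse onto the
disease indicator and individual β_gc are arbitrary splits of a common
disease effect. The packaged power experiment therefore draws compositions
with within-stage sd ≈ 0.08 (Dirichlet concentration 30) — the spread real
deconvolved cohorts display — and recovers the planted sign in ≥ 90% of
abundant-type genes at n = 80, |log2FC| = 1, φ = 0.1; the null experiment
at the same scale rejects at the nominal 5% rate.

Marker selection declares gene g a marker of type c when its cross-subject
mean count is ≥ 1 and ≥ 4× the maximum over other types (sets disjoint by
construction); marker/cluster overlaps are plain intersection counts.

## Ordinal scoring and lasso signatures

**Transform.** The variance-stabilizing stand-in is log2(CPM+1) —
deterministic, monotone, library-size invariant. Any user-supplied
variance-stabilized matrix can be substituted.

**Proportional-odds fits.** P(Y ≤ k | x) = σ(θ_k − βx) per gene, stages
coded 0..K−1 over the levels present (normal histology enters as the lowest
level). The fitter is implemented in-package: cutpoints parameterized as
(θ₁, log-increments) to stay ordered, stable log-likelihood via
σ(b) − σ(a) = σ(b)σ(−a)(1 − e^{a−b}), analytic gradient, L-BFGS-B on
internally standardized expression; statsmodels (`OrderedModel`, `Logit`)
is the independent oracle in the tests. Genes are flagged non-converged —
and excluded downstream — on optimizer failure, |standardized slope| > 30,
or a (near-)zero maximized log-likelihood, which signals perfect separation.
Constant genes get the zero-slope closed form θ̂_k = logit(P̂(Y ≤ k)).

**Scores.** The gene-level score is the expected stage level
Σ_k k·P̂(Y = k | x) ∈ [0, K−1] — the natural probability-weighted reading of
a model-based per-sample score. Genes are ranked by cv = sd/|mean| of their
scores (ddof 1; genes with |mean| < 1e-8 excluded; ties broken
lexicographically for determinism), and the composite sample score is the
mean over the top 1000 genes. Because null genes' scores are nearly
constant, averaging across them cancels their noise and the composite is
driven by the stage-informative minority.

**Lasso.** Predictors are standardized; the penalty grid holds 100
log-spaced values from λ_max = max|Xᵀ(y−ȳ)|/n down four decades; the path
is warm-started coordinate descent (scikit-learn's `lasso_path`), with λ = 0
falling back to least squares. λ selection rules: CV-MSE minimizer
(`min_mse`), largest λ within one standard error (`one_se`), or a requested
signature size (`target_size:k`, nearest achievable size with a warning).
k = 10 CV folds by default, seeded fold assignment; a separate 5-fold
re-validation of a chosen λ is provided. Signature sizes on synthetic data
are data-dependent; the published 26/98 sizes are fixture constants for set
arithmetic, not recovery targets. Scoring a matrix applies the training
standardization; missing signature genes contribute zero (warning; error
below 50% coverage).

**Trend clustering.** Differential genes are z-scored across samples,
reduced to per-stage mean trajectories, and clustered hierarchically
(correlation distance, average linkage, tree cut to a configured count,
default 6). Only clusters with strictly more than 50 genes are reported;
flat trajectories are labeled 0 and never reported.

## Numerical and I/O conventions

Deconvolution convergence: relative loading change < 1e-6, ≤ 100
iterations, stabilizer ν = 1e-8. Ordinal fits: ftol 1e-13 / gtol 1e-7
internally. All tabular output is written at 6 significant digits and is
re-readable by the package's own readers; sparse matrices use MatrixMarket
with plain-text row/column name sidecars (bulk TSV is genes-as-rows, MTX is
cells-as-rows). Pipeline stage seeds derive from the global seed via SHA-256
tags, so manifests reproduce checksum-identically.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` runs the cohort-scale analyses at the generator's
defaults (143 samples × 5000 genes, 6400-cell reference, 50 pseudo-bulk
mixtures of 400 cells), the regression calibration/power experiments at
n = 80 × 500 genes × 2000 tests, and the ImageScore at 25 repetitions of the
full 143-image tile set — sizes at which every stochastic quantity is stable
across seeds while the whole script completes in about a minute.

## What the synthetic benchmarks do and do not show

The generator plants exactly the structures the methods estimate: linear
mixing of type profiles, monotone tile features, log-linear planted effects.
Passing benchmarks therefore demonstrates correctness of the estimators
under their own assumptions — identifiability, calibration, recovery — not
performance on real tissue. Real data add ambient RNA, cross-platform and
cross-species reference mismatch, correlated gene modules, non-monotone
image artifacts and pathologist grading noise, none of which are modeled.
Two further limitations: the single synthetic reference stands in for the
published human/mouse reference integration (out of scope), and the
proportional-odds score treats stage spacing as exchangeable rank
information only.
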