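# fibroscope

A reusable pipeline for the transcriptomic characterization of liver fibrosis
in NAFLD/NASH. Liver biopsies are graded on the ordinal NASH CRN scale
(normal histology `N`, then fibrosis stages `F0`–`F4`), but the discrete
grade hides a continuous biological spectrum. `fibroscope` implements four
analyses that together connect bulk liver RNA-seq, single-cell references and
digital histology to that spectrum:

1. **ImageScore** — a continuous per-sample fibrosis severity learned from
   morphometric histology tile features (collagen areas, void/tissue
   compactness, …). Tiles are repeatedly down-sampled to 6 per image; in each
   repetition a 20-fold patient-level cross-validation fits PCA on training
   tiles, summarizes each patient as the median of their tiles' PC scores,
   and trains an RBF support-vector regression against numeric stage targets
   (N = −1, F0..F4 = 0..4). Each sample's final score is the median of its
   per-repetition held-out predictions.
2. **Cell-type deconvolution** — MuSiC-style consistency-weighted NNLS. From
   a multi-subject single-cell reference, per-type mean relative profiles
   θ̄\_gc, cross-subject variances v\_gc and cell-size factors S\_c are
   derived; each bulk sample y is decomposed by iterating

   &nbsp;&nbsp;q ← argmin\_{q≥0} Σ\_g w\_g (y\_g − Σ\_c θ̄\_gc q\_c)²,&nbsp;
   w\_g ← 1/(ν + Σ\_c q\_c² v\_gc),

   and reporting p\_c = (q\_c/S\_c)/Σ(q/S). A pseudo-bulk benchmark
   (resampled single cells with known composition) quantifies recovery.
3. **Cell-type-specific differential expression** — per gene, log2(TPM+1) is
   regressed on estimated proportions plus proportion × disease interactions
   (disease = F3/F4, control = F0/N, sex as covariate), so each interaction
   coefficient is a cell-type-specific log2 fold change; BH correction is
   applied across all (gene, cell type) tests.
4. **Gene signatures** — per-gene proportional-odds models
   P(Y ≤ k | x) = σ(θ\_k − βx) of stage on variance-stabilized expression
   yield per-sample expected-stage scores; genes are ranked by the
   coefficient of variation of those scores; the mean over the top 1000 genes
   is a composite fibrosis score; lasso regression of the composite on
   expression (10-fold CV over a 100-point λ path) produces sparse gene
   signatures that can score external cohorts.

A first-class synthetic-data module generates the whole study — stage-shaped
cohort (143 samples: 31 N, 35 F0, 30 F1, 27 F2, 8 F3, 12 F4), multi-subject
single-cell reference with planted markers, negative-binomial bulk mixtures
with planted stage-monotone and cell-type-specific effects, and severity-
monotone tile features — so every stage is testable against known truth.

## Worked example

```python
from fibroscope import StudyConfig, generate_study
from fibroscope.deconv import build_design, deconvolve, associate_proportions
from fibroscope.signature import (transform_expression, fit_ordinal_per_gene,
                                  gene_level_score, composite_score,
                                  fit_lasso_signature, score_and_validate)

study = generate_study(StudyConfig(n_genes=1000, seed=42))
design = build_design(study.reference)
est = deconvolve(study.bulk_counts, design)
assoc = associate_proportions(est.proportions, study.metadata)
print(assoc["stage_means"].round(3))

vst = transform_expression(study.bulk_counts)
fits = fit_ordinal_per_gene(vst, study.metadata["stage"])
scores = gene_level_score(fits, vst)
comp = composite_score(scores, top_n=200, stages=study.metadata["stage"])
print(f"composite score vs stage: Kendall tau = {comp.tau_vs_stage:.2f}")
sig = fit_lasso_signature(vst, comp.per_sample, folds=10,
                          lambda_rule="target_size:26", seed=42)
val = score_and_validate(sig, vst, stages=study.metadata["stage"])
print(f"{len(sig.genes)}-gene signature, tau vs stage = {val['tau_vs_stage']:.2f}")
```

prints

```
       hepatocyte  cholangiocyte    HSC  macrophage
stage
N           0.696          0.042  0.100       0.162
F0          0.647          0.046  0.134       0.172
F1          0.597          0.071  0.131       0.201
F2          0.524          0.089  0.152       0.235
F3          0.447          0.120  0.182       0.251
F4          0.354          0.161  0.236       0.248
composite score vs stage: Kendall tau = 0.87
26-gene signature, tau vs stage = 0.85
```

The deconvolved per-stage mean proportions show the expected biology —
hepatocytes fall from ~70% to ~35% across the fibrosis spectrum while
cholangiocytes, hepatic stellate cells and macrophages expand — and the
ordinal composite score and the 26-gene lasso signature both rank samples
in close agreement with histology.

A `fibroscope` CLI wraps each stage (`simulate`, `imagescore`, `deconvolve`,
`pseudobulk-benchmark`, `ctde`, `signature`, `run-all`); `run-all` executes
the whole pipeline and writes a manifest with per-stage timings and output
checksums.

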