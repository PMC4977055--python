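# Methods

This note documents the models, estimators, and design choices behind
`refewas`, in the order data flows through the pipeline.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with every injected effect recorded in a `SimTruth` object so that
downstream stages can be tested in closed loop.

**Methylation model.** Beta values arise as

    beta_ij = clip( Σ_k w_ik μ_jk + θ_j e_i + a_{p(i)} + ε_ij , [0, 1] )

with cell-type methylomes μ (K × loci), per-sample proportions w on the
simplex, direct exposure effects θ at a designated locus set, per-plate
location shifts a and scale-multiplied Gaussian noise ε
(sd `noise_sd × plate_scale`). The model is linear on the beta scale
because the downstream inference reports effects as differences in
methylation fraction per unit exposure. A warning is raised when more
than 10% of values clip.

**Methylomes.** A base methylome is drawn from a Beta mixture
concentrated near 0 and 1 with a ~20% minority of intermediate loci,
reproducing the bimodality of array data. Only a designated set of
*marker* loci (default 500 of 5,000) carries strong cell-type contrast
(per-cell-type offsets, sd 0.25); the remaining loci carry a small
background contrast (sd 0.02, configurable to 0). Direct-effect,
marker, and promoter-block loci are forced to intermediate base levels
(0.2–0.8) so injected effects are not distorted by clipping.

**Cell proportions.** Each sample draws base weights g ~ Dirichlet(α)
(default K = 4, α = (6, 2.5, 1, 0.5): one dominant cell type, three
minor ones; the trophoblast/stromal/Hofbauer/endothelial labels are
cosmetic). Exposure shifts composition through the softmax of
perturbed log-weights, w = softmax(log g + e·γ), which keeps proportions
exactly on the simplex for any effect size γ (default (0.4, −0.4, 0, 0)
per exposure unit).

**Ground-truth confounding labels.** For each locus the generator
records the population *mediated slope* — the derivative of
mixture-mean methylation with respect to exposure acting only through
the proportion shift, computed as Σ_k c_k μ_jk where c_k is the
regression slope of E[w_k] on exposure evaluated by a high-precision
Monte-Carlo draw (n = 20,000) from the generator's own model. A locus
is labeled *proportion-mediated* when |mediated slope| ≥ 0.002, i.e.
when composition induces an apparent effect at least as large as the
reference direct effect; direct-effect and promoter-block loci are
excluded from the label so the two classes are disjoint. For
confounding-separation studies the background contrast is set to 0:
with nonzero background contrast every locus (including direct-effect
loci) is genuinely mildly confounded and a clean mediated/direct
dichotomy does not exist.

**Exposures.** Three biomarkers (placenta, toenail, urine µg/kg or
µg/L) are correlated lognormals on the log scale, with meanlog/sdlog
matched to the cohort medians and IQRs (placenta median 0.82, toenail
0.05, urine 3.76) and target log-scale Pearson correlations
(0.03, 0.03, 0.19). Urinary arsenic is split into four species
(arsenate, arsenite, MMA, DMA) by a Dirichlet speciation with mean
shares (4, 4, 5, 87)% chosen so the below-detection-limit rates at DLs
of 0.10–0.15 roughly reproduce the observed censoring pattern (about
half of arsenate/arsenite censored, a fifth of MMA, almost no DMA).
Species below their DL are emitted as missing with a below-DL flag.
Per-biomarker missingness masks default to the 285/257/271-of-343
availability pattern. The placenta value (pre-censoring truth) drives
the methylation simulation.

**Promoter block.** Eleven adjacent probes (~600 bp span, one gene,
island/TSS annotation) share a per-sample random factor (sd 0.03) and a
direct effect (−0.003), producing strongly positively correlated probes
whose mean tracks exposure — the substrate for the tertile/expression
analysis. Expression is linear in mean block methylation with slope
derived from a target correlation (−0.15) given the realized
methylation spread and the noise sd; it is emitted as paired qPCR Ct
values such that 2^−(Ct_target − Ct_housekeeping) recovers it.

**What the generator does not emulate:** probe-type (I/II) chemistry,
spatial chip artifacts, non-Gaussian noise, genuine biological
covariate effects (maternal age, gestational age and sex are simulated
independent of methylation), GO-graph structure (terms are random sets
plus two terms deliberately enriched for mediated loci), and raw-
intensity-level processing. Passing tests therefore demonstrate the
statistical machinery under its assumed model, not robustness to every
artifact of real arrays.

## Preprocessing

**Filtering.** Four rules — X/Y chromosome, cross-reactive, SNP flag,
detection p > 0.01 in ≥ 1 sample — applied with a fixed precedence
(XY → cross-reactive → SNP → detection) so each removed probe is
counted exactly once; the order is a reporting convention, the retained
set is order-independent. SNP/cross-reactive status is taken from
annotation flags (plus an optional extra id list); no MAF or distance
criterion is imposed.

**PCA diagnostics.** PCs of the locus-centered matrix over samples;
per-PC one-way ANOVA of scores on a technical label. The number of
inspected PCs (default 2) and the test are explicit parameters.

**Batch adjustment.** Parametric empirical-Bayes location/scale
harmonization: per-locus standardization with a design preserving
biological covariates; per-plate locus-wise means and variances shrunk
toward moment-matched normal and inverse-gamma priors via the iterative
posterior solution (tolerance 1e-8); back-transformation. Parametric
rather than nonparametric priors: simpler, adequate for location/scale
shifts, and testable in closed loop (a unit test checks agreement with
scanpy's implementation to 1e-4). Adjusted values are deliberately
**not clipped** to [0, 1]: clipping would bias locus means consumed by
the linear models, and excursions are bounded by a few noise sds.

## Reference-free EWAS

**Design.** Intercept, one exposure biomarker (untransformed by
default; a log10 switch exists because the original analyses
log-transform for correlations but report per-unit effects), maternal
age and gestational age continuous, infant sex binary. Samples missing
the exposure or a covariate are dropped, so each biomarker's fit runs
on its own subset.

**Dimension selection.** d = number of eigenvalues of the residual
sample-correlation matrix above the Marchenko–Pastur upper edge for the
effective aspect ratio (n − p)/m, rescaled by n/(n − p) for the rank
deficit the regression introduces and padded by a Tracy–Widom
fluctuation term (99th-percentile slack, `TW_SLACK = 2.02`). On pure
noise this yields d = 0 in ≥ 95% of draws; on K = 4 mixtures it finds
the K − 1 free proportion dimensions plus any shared-factor structure.
A manual override is always available.

**Identification of β\*.** The latent term is estimated from the
rank-d singular structure of the covariate residuals (alternating
least squares = orthogonal subspace iteration, SVD-initialized;
convergence measured as max |Δβ\*| < 1e-6, ≤ 100 iterations). The
adjusted coefficients are

    β* = β̂ − Λ (ΛᵀΛ)⁻¹ Λᵀ β̂ ,

i.e. the component of the coefficient field lying along the cell-type
loadings (in locus space) is attributed to composition. This
projection is what identifies the β/β\* split: the least-squares
objective alone cannot allocate a latent component correlated with the
design between B and ΛUᵀ (any part of ΛUᵀ inside span(X) is freely
absorbed by B), so a "joint ALS" estimate of β\* is either degenerate
or identical to β̂ depending on initialization. The projection
attributes to cell mixture exactly the coefficient structure that looks
like cell-type methylome contrasts, which is the substance of the
reference-free deconvolution approach. With d = 0, β\* ≡ β̂ on the same
arithmetic path.

**Bootstrap inference.** Nonparametric resampling of samples (columns
of Y with matching design rows; rank-deficient redraws capped at 100),
default 200 replicates; each replicate refits β̂ and β\* at fixed d with
the subspace iteration warm-started from the point fit's scores.
SE = replicate standard deviation; p = 2Φ(−|estimate/SE|); the
per-locus Cov(β, β\*) of the exposure column is retained for the δ
test. BH q-values (canonical step-up, monotone, capped at 1) and
Bonferroni-adjusted p are reported; genome-wide thresholds default to
q < 0.05 and p < 1.0×10⁻⁷.

**Known limitation — far-tail calibration under heavy-tailed
exposure.** The pair bootstrap is first-order equivalent to the HC0
sandwich estimator. With a right-skewed (lognormal) exposure a typical
n = 200 draw contains a high-leverage sample (h ≈ 0.2), where the
realized squared residual underestimates the noise variance by a factor
(1 − h); the bootstrap SE is therefore systematically a few percent
low, which is irrelevant at the 0.05 level (the pooled null fraction of
p < 0.05 stays near 0.055) but inflates the extreme tail that a
5,000-test FDR correction interrogates: under a pure null, isolated BH
false discoveries appear in a substantial minority of cohort draws.
Log-transforming the exposure (config switch) largely removes the
leverage and with it the effect. This is a property of
bootstrap-normal p-values with heavy-tailed regressors, not of the
latent adjustment (the unadjusted model shows it equally).

## Confounding statistic and enrichment

δ = β\* − β with SE from the bootstrap variances and covariance;
z = δ/SE, p = 2Φ(−|z|); loci with Bonferroni-adjusted p < 0.10 are
flagged confounded (the Bonferroni reading governs over a bare
p < 0.10). Degenerate SE = 0 cases: p = 1 when δ = 0, p = 0 with a
warning otherwise.

The CMH statistic over S strata (island relation × gene region, up to
24; a probe with several region annotations takes the most
promoter-proximal) uses the Cochran variance

    χ² = ( Σ_s (a_s − E[a_s]) )² / Σ_s r1_s r2_s c1_s c2_s / n_s³ ,

so that with a single stratum it reduces *exactly* to the Pearson
chi-square without continuity correction; the Mantel–Haenszel common
odds ratio (Σ a d/n) / (Σ b c/n) is reported alongside, and both are
labeled unambiguously. Strata whose 2×2 table has a zero margin are
pooled into the nearest non-degenerate stratum (same gene region,
nearest island relation first), terms with fewer than 5 member loci are
skipped, and significance is Bonferroni p < 0.05 over tested terms.

## Targeted lookup and expression

Candidate loci are re-tested with plain per-locus OLS (classical
t-test, n − p df) and **no multiplicity adjustment** — they are
specified a priori; probes absent from the filtered matrix are reported
as missing rather than errored. Tertile selection takes the bottom and
top ceil(n/3) samples by value with sample-id tie-breaking (exactly 64
of 96), making the selection deterministic and negation-symmetric.
Relative expression is 2^−(Ct_target − Ct_housekeeping) (single-plate
relative quantification against a stable housekeeping gene); records
with a missing Ct are excluded and counted. The Pearson correlation is
computed on the selected extreme-tertile subset, replicating — not
correcting — the selection design of the original analysis; raw
expression is the default with a log2 switch.

## Pipeline

Stages run in the order simulate → preprocess → exposure → EWAS (one
fit per biomarker) → δ/enrichment → targeted/expression. The master
seed fans out through `SeedSequence(master, spawn_key=(stage_index,))`
(all derived seeds < 2³¹), so stage seeds are independent and rerunning
a configuration is byte-identical (timestamps only in the log). Every
output table carries a header comment with the configuration hash
(output-path excluded) and seed; the summary is recomputed purely from
the output TSVs, so an independent reader can re-derive every count.

## Problem sizes

Simulation studies in the test suite and acceptance script use
5,000-locus × 200-sample cohorts for calibration checks, 2,000 × 300
for recovery and confounding separation, and ~2,500 × 250 for the
end-to-end demo — scaled-down panels that preserve the aspect ratios
and noise levels at which the estimators operate, chosen so the full
closed loop runs comfortably on a single CPU.
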