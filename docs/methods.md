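# Methods

`npxbio` implements a biomarker-discovery workflow for targeted plasma
proteomics (Olink-style PEA panels reporting NPX, a log2-scale relative
abundance unit) applied to a four-group case–control design: cutaneous
mastocytosis (CM), indolent systemic mastocytosis (ISM), advanced
systemic mastocytosis (AdvSM), and a polycythemia-vera (PCV) reference
group without mast-cell disease. This note describes the models and
procedures, the choices made where the design was open, and what the
synthetic-data tests do and do not establish.

## Data model and preprocessing

An `NpxMatrix` is a samples × assays table of NPX values with two masks:
missingness (NaN) and below-LOD (value reported but under the assay's
limit of detection). The preprocessing rules are deliberately
conservative:

* **Cross-panel duplicates.** A protein measured on two panels is kept
  once: the copy with the smaller fraction of below-LOD values (over
  non-missing entries) survives. With the default three 92-assay panels
  and one duplicated protein this takes 276 assays to 275. Exact ties
  keep the lexicographically first panel and log a warning.
* **Low-detection flagging.** Assays with strictly more than 20% of
  their observed values below LOD are flagged (the "‡" set) but their
  values are retained unchanged — no LOD substitution. The flag
  propagates into the differential tables so readers can discount those
  rows.
* **QC failures.** Samples with QC warnings are flagged
  (`qc_pass=False`) and retained.
* **Imputation** (only where a complete matrix is needed, i.e. PCA):
  iterative (EM) PCA. Missing cells start at column means; each
  iteration centers and unit-scales the completed matrix, reconstructs
  it at rank `ncp`, and overwrites only the missing cells, until the
  summed squared change of the imputed cells falls below `tol`
  (default 1e-12 — tight enough that a rank-1 matrix with one deleted
  entry is recovered to better than 1e-6; looser tolerances stop an
  order of magnitude short). `ncp` defaults to 2, the dimensionality of
  the score plane that is actually interpreted; it is configurable, and
  a regularized variant (singular-value shrinkage) is available for
  noisier data. Observed values are never altered.

## Ordination and the permutation centroid test

PCA follows `prcomp` conventions: per-assay centering, scaling by the
n−1 sample SD, scores from the SVD of the scaled matrix, components
ordered by explained variance. Group centroids are arithmetic means of
score vectors.

Whether two diagnosis groups separate is tested by the Euclidean
distance between their centroids in a chosen score subspace (default
PC1/PC2, the plotted plane; configurable and recorded in the result).
The null distribution shuffles the two group labels over the pooled
samples (sizes preserved) and recomputes the distance **on the fixed
score matrix** — PCA is label-blind, so refitting per permutation would
reproduce the same null at ~100× the cost. The p-value is the add-one
upper-tail estimate (r+1)/(n_perm+1), which cannot be exactly zero; with
n_perm = 999 the attainable floor is 1/1000. Samples outside the two
groups are excluded from the test. Calibration is verified by
simulation: on null cohorts (42 samples, 200 proteins) the empirical
type-I error at α = 0.05 sits inside the 99% binomial band over 500
replicates.

## Differential abundance

Per protein, a Welch two-sample t-test (unequal variances — the group
sizes here differ by up to 7×) with Welch–Satterthwaite degrees of
freedom; missing values are excluded pairwise, with no imputation for
testing. Because NPX is log2-scale, the mean difference is the log2
fold change, so the volcano classification is just sign(estimate) at
q < 0.05. The BH family is all proteins of one contrast, not pooled
across contrasts (each contrast is reported as its own figure/table).
Demographics use the χ² test of independence without continuity
correction (categorical) and Kruskal–Wallis H (continuous).

## All-relevant feature selection (shadow features)

Before selection, each protein is residualized on age and sex
(per-assay OLS, intercept included; sex coded F=1), because age
confounds diagnosis in this design (AdvSM and PCV patients are older).
Remaining missing values are replaced by per-assay medians (the
random-forest "rough fix"). The selection loop itself:

1. each *active* (not-yet-rejected) feature gets a fresh shadow — an
   independently permuted copy, pure noise with the same marginal —
   padded to a minimum of 5 shadows;
2. a random forest (default 500 trees, √p features per split,
   unlimited depth) is fit on [real ∪ shadow] features;
3. importance Z = mean per-tree out-of-bag permutation importance
   (mean decrease in accuracy when one feature's OOB values are
   permuted) divided by its standard error over trees;
4. an undecided feature scores a hit when its Z exceeds the best
   shadow Z;
5. hit counts are referred to Binomial(n_iter, ½) with one-sided tests
   in both directions, Bonferroni-corrected over the undecided
   features at α (default 0.01, the reference implementation's
   default): significantly high → Confirmed, significantly low →
   Rejected, else Tentative.

Rejected features are dropped from later forests; Confirmed features
**stay in the forest** (as in the reference implementation) but are no
longer tested — keeping them lets them continue to absorb the signal
they carry, which measurably reduces spurious confirmation of
weakly chance-correlated noise. Tentative features are reported as
such, never forced. Iteration-level decisions are logged at INFO.

A caveat the procedure cannot escape: "all-relevant" means relevant *in
the dataset at hand*. With ~100 samples, a noise feature whose sample
correlation with the label is large by chance is genuinely informative
in-sample and is occasionally confirmed; simulations here show ≤1 such
confirmation per run on 50-noise-feature data, and a mean well under 1
on pure noise.

## Logistic biomarker models

Each candidate marker is assessed in `logit P(group₁) = β₀ + β_age·age
+ β·NPX`, fit by plain maximum likelihood (no Firth penalization —
matching the modelling convention the workflow follows; with 12 AdvSM
cases quasi-separation is a real possibility and is *flagged*, not
penalized away: non-convergence or |β| > 15 marks the row). Reported:
β, SEM from the observed information, OR = exp(β) per +1 NPX (per
doubling of concentration), 95% CI = exp(β ± 1.96·SEM), Wald p per
marker, and the in-sample C-index (Harrell's concordance of predicted
probabilities, ties = ½, computed by the midrank identity and verified
against exhaustive pair counting). The stepwise table adds markers in a
given order, reporting ΔC against the previous model and the
likelihood-ratio χ² (df = number of added terms) for each addition.
In-sample C is optimistically biased by construction; no
cross-validation is attempted, and on strongly separable synthetic data
the combined model reaches C = 1.0, which should be read as a ceiling
artifact, not performance.

Outcome coding: the first-listed group of a contrast is 1, so markers
elevated in the second group get OR < 1.

## Single-cell linkage

Given an annotated, normalized log-transformed expression matrix, each
gene × cell-type cell of the dot-plot grid carries: the mean expression
over cells of the type; the gene-wise Z of those means across types
(population-SD standardization — with ~6–10 cell types the n vs n−1
choice is material, and the convention is recorded on the result
object; a gene with constant means gets Z = 0); and the fraction of
cells with expression strictly > 0 ("expressing" — no minimum
threshold). Genes are ranked per cell type by mean expression,
ties alphabetical. Cells lacking annotation are dropped with a logged
count; >50% unannotated barcodes aborts, as that indicates mismatched
files. UMAP coordinates are never computed, only joined if supplied.

## Synthetic data: what it emulates, what it does not

The cohort generator reproduces the *statistical skeleton* of the
study: group sizes 16/80/12/60; 3 panels × 92 assays with one protein
(IL6) on two panels; Gaussian baseline NPX per assay (assay means drawn
once from N(5, 1), unit residual SD) plus additive per-(assay, group)
shifts; per-assay LODs placed at a quantile of the baseline (default
0.02, with two assays censored at the 30th/25th percentile so the >20%
rule has live targets, and the duplicated assay's second copy censored
strictly harder so the resolver's choice is determined); MCAR
missingness (default 1%); exactly 5 QC-failed-but-retained samples;
triangular age distributions matching each group's published median and
range (only those three numbers are published); and per-group sex
ratios. An optional equicorrelated protein block exists but is off by
default — no correlation values are published to emulate.

Not emulated: plate effects and bridging normalization, LOD-censored
*value* distortion (values below LOD are drawn from the same Gaussian),
protein–protein correlation structure, non-Gaussian tails, or any
clinical-symptom structure. Passing tests therefore demonstrate
correctness of the procedures and their calibration under clean
Gaussian conditions, not robustness to real Olink artifacts.

The single-cell generator draws exponential expression (mean 0.5) with
multiplicative fold elevation for planted markers in their designated
cell type and independent dropout zeros. It emulates marker contrast
and sparsity, not counts, library-size variation, or batch structure.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to give stable pass/fail
behavior: permutation calibration uses 500 null cohorts of 42 × 200
with 499 permutations; selection recovery uses 10 seeds of 100 × 53
with 60-iteration, 300-tree runs; Wilks calibration uses 1000
simulations at n = 150. Library defaults remain at full scale
(n_perm = 9999, maxRuns = 500, 500 trees).

## Known limitations

* The permutation test is pairwise only; no multi-group partitioning.
* Tentative features have no forced resolution; downstream stages take
  Confirmed sets only.
* The iterative-PCA imputer assumes approximate low-rank structure;
  with `scale=True` and near-constant assays the scaling step can
  amplify noise (guarded by a positive-SD floor).
* In-sample C-indexes and ORs from quasi-separated fits should be
  treated as exploratory, exactly as flagged in the output.
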