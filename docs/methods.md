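# Methods

This note documents the statistical models implemented in `twasmr`, the
synthetic data they are validated on, the tunable parameters that matter,
and the design choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic study generator (`twasmr.simulate`)

The generator emulates the statistical structure of a TWAS + MR study of a
case-control trait: an expression training cohort genotyped on the same
variant panel as one or more GWAS cohorts, LD-blocked common variants,
sparse cis-genetic control of expression, and a disease liability mediated
by one gene's genetically determined expression.

### Genotypes

Variants are laid out on one chromosome at `variant_spacing_bp` (default
25 kb) in blocks of `ld_block_size` (default 5). Within a block each of an
individual's two haplotypes is a stationary two-state Markov chain with
marginal allele frequency `p` (one MAF per block, drawn from `maf_range`,
default (0.1, 0.5)) and transition probabilities

    P(1 -> 1) = p + rho (1 - p),    P(0 -> 1) = p (1 - rho),

which give lag-k haplotype correlation `rho^k` exactly. Summing the two
haplotypes yields Hardy–Weinberg genotypes whose correlation is also
`rho^k` in expectation — the AR(1) target holds in closed form *on the
genotype scale*. An alternative construction (thresholding a correlated
Gaussian at genotype-frequency quantiles) was rejected because
discretization attenuates the correlation by a MAF-dependent factor of
roughly 0.7–0.9 per variant, so a latent correlation of 0.9 cannot deliver
genotype r² above ~0.55; the Markov-chain coupling has no such ceiling.
The block-level (rather than per-variant) MAF is what makes the coupling
exact; blocks are mutually independent.

### Expression

Genes tile the panel: each owns a contiguous variant window with its gene
body in the central third, and its cis region is the body ± 1 Mb.
Per gene, `round(causal_fraction * window)` causal variants are drawn; the
matrix of their effects across tissues is Gaussian with cross-tissue
correlation equal to the supplied tissue-similarity matrix (so
similarity 1 means identical effect vectors and similarity 0 independent
ones). Expression in tissue t is

    y_t = sqrt(h2) * g_t / sd(g_t) + sqrt(1 - h2) * e_t,

where `g_t` is the genetic value on standardized dosages and `e_t` is a
unit-variance mix of covariate signal (two simulated PCs and a sex
indicator, weight `covariate_share`, default 0.2) and Gaussian noise. The
regression R² of expression on the true genetic value therefore equals the
`heritability` parameter by construction, and the recorded ground-truth
weights (effects per SD of dosage) are on the same scale as trained model
weights.

### Phenotypes and summary statistics

Case-control traits follow a logistic model: `logit P(case) = alpha +
gene_effect * g_std + X_std delta`, where the direct effects `delta ~
N(pleiotropy_mean, pleiotropy_sd)` live on a `pleiotropy_fraction` subset
of (by default cis) variants — the invalid instruments. `alpha` is solved
numerically for the target `prevalence` (default 0.5, i.e. a case-control
design with matched sampling); an all-case/all-control draw raises with a
diagnostic. GWAS tables come from per-variant marginal regressions: a
vectorized Newton (IRLS) logistic solver for binary traits (validated
against `statsmodels.Logit` in the test suite) and closed-form OLS with
t-tests for quantitative ones. Monomorphic variants are emitted with NaN
statistics, never dropped. Scenario presets cover the global null,
gene-mediated (vertical) causality, directional pleiotropy, and balanced
invalid instruments at 20%/40%.

For MR estimator calibration a second, instrument-level generator
(`simulate_iv_summary`) draws harmonized summary statistics directly:
exposure effects `gamma_j ~ U(0.1, 0.3)` observed with SE `1/sqrt(20000)`,
outcome effects `theta * gamma_j` plus direct effects on the invalid
subset, observed with SE `1/sqrt(50000)` — trait-GWAS-scale noise levels.

### What the generator does not emulate

Real LD is not AR(1) and real MAF varies within haplotype blocks; there is
no population structure beyond the two simulated PCs, no genotyping error
or imputation uncertainty, no PEER-style latent expression confounders
(top expression PCs are available as a substitute via
`models.expression_pcs`), and binary traits are logistic rather than
liability-threshold (chosen so the simulated effects live directly on the
log-OR scale of the GWAS summary statistics). Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not robustness to every artifact of real cohort data.

## 2. Prediction models (`twasmr.models`)

All frameworks operate on covariate-residualized expression (OLS
projection; rank-deficient covariate sets are rejected with the collinear
columns listed), standardize dosages to unit variance, and report weights
on the standardized-dosage scale. Cross-validation folds come from one
seeded permutation and are shared across frameworks so their out-of-fold
(OOF) accuracies are comparable. `cv_p` is the two-sided t-test on the OOF
Pearson correlation — the natural test for a correlation-based
imputability rule (`cv_r > 0.1` and `cv_p < 0.05`).

* **Elastic net** (single tissue): objective
  `(1/2n)||y - Xb||^2 + lambda [alpha ||b||_1 + (1-alpha)||b||_2^2 / 2]`,
  `alpha = 0.5` by default, with lambda chosen on a 50-point log grid from
  the data-dependent `lambda_max` down four orders of magnitude. An
  all-zero fit is returned with `cv_r = 0`, flagged non-imputable, and is
  not an error.
* **Cross-tissue sparse-group lasso**: joint objective
  `sum_t (1/2 n_t)||y_t - X b_t||^2 + lambda1 sum |b_jt| + lambda2 sum_j
  ||b_j.||_2`, solved by proximal gradient descent (ISTA, fixed step 1/L)
  whose prox — entrywise soft-threshold, then per-SNP group shrinkage — is
  exact, giving guaranteed monotone descent. One `(lambda1, lambda2)` pair,
  selected by pooled OOF loss over a small factorized grid, is used in
  every fold. With `lambda2 = 0` and one tissue the fit matches a plain
  lasso to 1e-4.
* **Similarity-weighted elastic net**: all tissues' samples stacked with
  sample weights `s(target, t)^p`, `p` selected from {1, 4, 16} by OOF
  accuracy in the target tissue; folds are split by donor so no donor is on
  both sides of a fold. With the identity similarity this reduces exactly
  to the target-tissue elastic net (same code path, zero-weight rows
  dropped).

The best model per gene is the argmax of `cv_r`; exact ties break by a
fixed framework order; a non-imputable best yields no model for that gene.

## 3. Summary-statistic TWAS (`twasmr.twas`)

With raw-dosage-scale weights `a_l` (standardized weights are converted by
`a_l = w_l / sigma_l`), panel SDs `sigma_l` and correlations `rho`:

    z_g    = sum_l a_l sigma_l z_l / sigma_g
    sigma_g^2 = sum_{l,l'} a_l a_l' sigma_l sigma_l' rho_ll'
    beta_g = sum_l a_l sigma_l^2 beta_l / sigma_g^2,   se_g = beta_g / z_g

GWAS records are aligned to the model's effect allele before use. Model
variants missing from the GWAS are dropped with the retained absolute
weight fraction reported; below 80% coverage the gene is flagged. The
variance source is deliberately the LD panel alone (never GWAS allele
frequencies) so one panel supplies both `sigma_l` and `rho`. A
non-positive `sigma_g^2` (an inconsistent externally supplied correlation
matrix) is an error; zero overlap raises a typed exception that scan
drivers convert to a skip record. `z_to_p` uses the normal survival
function directly (no 1 - CDF cancellation) and offers a log-scale output
for |z| beyond the double-precision floor near 38.5. BH adjustment is the
step-up rule with an explicit family size `m_total >= #supplied`, so the
published-table reconstruction (top genes of a 9952-gene family) is a
direct call.

## 4. Mendelian randomization (`twasmr.mr`)

Instruments: exposure records with P below the threshold (5e-8 for traits;
1e-5 for cis-eQTL exposures in the pipeline, since an n≈300 expression
cohort cannot reach 5e-8 and 1e-5 is the conventional eQTL-instrument
choice), greedily clumped to pairwise r² < 0.01 within 250 kb
(P-ascending, ties by position; window center-to-center, inclusive),
optionally restricted to or stripped of a gene locus (body ± 1 Mb,
boundaries inclusive), then harmonized to the outcome GWAS. Estimation
refuses fewer than three independent instruments — a refusal is a typed
exception carrying the surviving count, never a silent estimate.

* **Wald ratios**: `theta_j = beta_out_j / beta_exp_j` with first-order SE
  `se_out_j / |beta_exp_j|` (exposure uncertainty ignored; instruments are
  genome-wide significant by construction, so the second-order term is
  negligible). Zero-exposure instruments are excluded with a reason.
* **IVW**: inverse-variance mean of ratios, equal to origin-constrained
  WLS of outcome on exposure effects with weights `1/se_out^2`.
* **Weighted median**: ratios ordered, cumulative normalized weights with
  the midpoint convention, linear interpolation at 0.5; SE from a
  parametric bootstrap (default 1000 replicates; fewer than 100 is
  rejected) redrawing both effect sets from their sampling distributions.
* **MR-Egger**: exposure effects oriented non-negative, then WLS of
  outcome on exposure effects *with* intercept, weights `1/se_out^2` and a
  multiplicative residual-dispersion factor floored at 1. The slope is the
  causal estimate; the intercept estimates average directional pleiotropy
  with its own normal test.
* **Heterogeneity-penalized**: `beta_out_j = theta beta_exp_j + phi_j`,
  with each instrument's direct-effect term `phi_j` shrunk by an L1
  penalty (exact alternating minimization: soft-threshold for `phi`, WLS
  for the never-penalized `theta`); the penalty is chosen by
  cross-validation over instruments, predicting held-out outcome effects
  from the causal term alone. With no pleiotropy all `phi_j` shrink to
  zero and the estimate reduces to IVW; an outlying instrument absorbs its
  own heterogeneity instead of biasing `theta`. CI by parametric
  bootstrap. This implements the per-instrument-heterogeneity idea behind
  MR-JTI as a faithful-in-spirit reimplementation, not a line-by-line
  port; the penalty grid and bootstrap count are exposed in the signature.

All estimators are invariant to per-instrument allele recoding (flipping
both effect signs), verified by test.

### Calibration study conditions

The standing calibration studies (`twasmr.validation`) use 30 independent
instruments. This count matters: the weighted median is consistent only
while the *weight* fraction of invalid instruments stays below one half,
and with 40% invalid by count the invalid weight fraction concentrates
below 0.5 only for instrument sets of roughly this size (with 15
instruments it crosses 0.5 in ~15% of draws and no correct implementation
can keep the mean bias small). Thirty genome-wide-significant instruments
is also a realistic scale for a well-powered trait GWAS. The Egger
coverage study puts an independent `N(0.1, 0.05)` direct effect on every
instrument (the InSIDE condition) and checks nominal 95% coverage of the
intercept.

## 5. PheWAS (`twasmr.phewas`)

One summary TWAS of the selected gene model per catalog phenotype, with BH
adjustment *across phenotypes within the scan* (the correction scheme is a
design choice; the threshold is exposed). Phenotypes with no overlapping
variants are reported as skipped. Results are sorted by P with a
direction column (sign of z).

## 6. Pipeline (`twasmr.pipeline`)

`run_pipeline` executes: simulate one population and split it into an
expression-training cohort and a GWAS cohort (sharing the variant panel
and true effects) → per-sub-cohort GWAS and fixed-effect meta-analysis
(heterogeneity Q/I² reported but unused) → model training and selection →
summary TWAS against the meta-analysis → gene-level MR of
TWAS-significant genes (cis-eQTL instruments, three methods) →
bidirectional trait MR against a second, causally downstream trait, run
with all instruments, locus-restricted, and locus-excluded →
PheWAS of the top gene against a small catalog (the downstream trait, the
disease itself, and permuted-null traits). Every output is plain TSV with
≥4 significant digits plus a provenance JSON (config, seed, version) and a
per-stage log of record counts; a fixed seed reproduces all outputs
byte-for-byte, and a stage failure raises with the stage name while
preserving completed outputs.

Default vignette conditions: GWAS cohort 6000, training cohort 300
(matching the scale of a single-tissue expression reference), 300 variants
in 5-variant LD blocks, 10 genes, heritability 0.5, causal fraction 0.2,
gene effect 0.8 log-OR per SD of expression, 50% prevalence. These sizes
keep the full vignette around half a minute on one core while leaving the
planted gene clearly detectable.

**FDR family size.** The vignette simulates a handful of genes as a
stand-in for a transcriptome-wide scan, so the TWAS stage assesses BH
significance against a configured family size `m_total` (default 10,000,
the order of imputable genes in a transcriptome-wide analysis), not
against the simulated gene count. This matters for the null calibration
study: BH at FDR 0.10 applied to a *self-contained* global-null scan
declares at least one discovery in exactly 10% of scans (Simes'
identity) — that is what controlling FDR at 0.10 means, not a defect — so
the within-scan zero-discovery rate hovers at ~90% by construction and is
reported as a descriptive quantity, while the pass/fail check uses the
configured family size, under which a null vignette essentially never
declares a simulated gene significant. The sharp calibration check is the
uniformity of the raw TWAS p-values (KS test), which does not depend on
the family-size convention.

## 7. Numerical details and edge cases

- One seeded `numpy` Generator per run drives every random draw; derived
  seeds stay below 2^31.
- Logistic Newton steps are damped (max step 5 on the linear predictor
  scale) and fits with |log-OR| > 25 or non-finite curvature are reported
  as NaN (quasi-separation).
- Ties in clumping order break by (chrom, pos); ties in model selection by
  framework order — both for determinism.
- Palindromic (A/T, C/G) variants with exposure EAF in (0.4, 0.6) are
  dropped during harmonization as strand-ambiguous; the generator itself
  emits only non-palindromic allele pairs so simulated pipelines lose
  nothing.
- Degenerate inputs (empty instrument sets, all-zero weights, monomorphic
  panel variants, OR = 1 confidence intervals, z = 0) are either typed
  errors or explicitly flagged outputs, as documented per function.

## 8. Known limitations

- The cross-tissue solver is plain ISTA; for very large cis windows a
  FISTA/coordinate-descent scheme would converge faster (the problems here
  are small, so monotonicity was preferred over speed).
- Wald-ratio SEs are first-order; weak-instrument MR (conditional F < 10)
  is out of scope, as are multivariable MR and Steiger filtering.
- The PheWAS assumes phecode-labelled summary statistics as inputs; no
  ICD-to-phecode mapping is provided.
- Coordinates are 1-based inclusive throughout; only text dosage matrices
  are read (no VCF/PLINK binary parsing).
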