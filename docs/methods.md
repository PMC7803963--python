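# Methods

## The model

The pipeline treats each metabolite's (log10) level as an additive genetic
trait plus covariates and noise,

    log10 m_i = sum_j beta_j g_ij + c_i' gamma + e_i,

estimates per-SNP marginal effects by OLS in each cohort, combines cohorts by
fixed-effect inverse-variance weighting, learns a sparse-to-polygenic SNP
predictor of the metabolite by cross-validated penalized regression or
clumping-and-thresholding, and tests the genetically predicted metabolite
against a downstream phenotype using only that phenotype's GWAS summary
statistics. For SNP weights w and phenotype z-scores z, the association
statistic is

    Z = (w~' z) / sqrt(w~' R w~),     w~_j = w_j * sd_j,

where sd_j is the dosage standard deviation of SNP j in an LD reference panel
and R the panel SNP-SNP correlation matrix. Z is the z-score of the induced
score-phenotype covariance under the null of no association; when the model
has one SNP with nonzero weight it reduces exactly to that SNP's z. This
statistic is not derived from individual-level data — it is the standard
summary-statistic test for a linearly imputed intermediate trait, and is
documented here because the pipeline's validity rests on it. Two-sample MR
(Wald ratio / IVW / Egger / weighted median over the model's clumped SNPs)
provides an orthogonal estimate of the metabolite -> phenotype effect with
different identifying assumptions.

## Synthetic studies

The generator emulates a two-cohort metabolomics study design:

* **Genotypes.** One latent standard normal per SNP, AR(1)-correlated within
  LD blocks, thresholded at Hardy-Weinberg cutpoints for the block's MAF
  (drawn uniformly from `maf_range`, shared within a block — near-perfect LD
  forces near-equal allele frequencies, as in real haplotype blocks). The
  latent correlation of each adjacent pair is calibrated by bisection on
  bivariate-normal orthant probabilities (Owen's T) so the **genotype**
  correlation equals `ld_rho`; plain thresholding would attenuate it. Latent
  correlation is capped at 0.9999, so extreme targets with mismatched MAFs
  are unattainable by construction. Blocks sit 2 Mb apart (beyond the
  clumping window) with 10 kb spacing inside a block; positions are 1-based
  on synthetic chromosomes. Only non-palindromic allele pairs are emitted
  (ambiguous SNPs are dropped during harmonization anyway).
* **Metabolites.** Each metabolite's log10 level is a genetic score over
  `n_causal_snps` random SNPs, rescaled so its sample variance equals the
  target heritability `h2`, plus small age/sex effects, a cohort batch shift
  (0.1 on the log10 scale), and Gaussian noise of variance 1 - h2. Published
  CSF studies could not estimate metabolite heritabilities reliably, so the
  default h2 = 0.3 with one causal SNP is an engineering choice: strong
  enough that a trained model passes the R^2 > 0.025 inclusion filter at
  n ≈ 600, weak enough that the GWAS/meta stages are still exercised with
  realistic noise.
* **Missingness.** Non-xenobiotics are left-censored below their
  `missingness_rates["nonxeno"]` quantile (missingness = below detection
  limit, which is exactly the assumption half-minimum imputation makes);
  xenobiotics go missing in whole samples at random (genuine absence).
* **Phenotype GWAS.** A fresh cohort of `phenotype_gwas_n` individuals is
  drawn from the same SNP panel; the phenotype is
  `effect x (true genetic score of the metabolite) + N(0,1)`, and marginal
  per-SNP regressions are emitted for every SNP.

What the generator does **not** emulate: realistic human LD maps and MAF
spectra, genotype imputation quality, population stratification (beyond what
PCs would absorb), assay batch drift beyond a mean shift, and correlated
metabolite networks. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artefact of real cohort data.

## Numerical and procedural choices

* **GWAS.** Per-SNP OLS is computed by Frisch-Waugh-Lovell residualization
  (algebraically exact, vectorized over SNPs); p-values come from the t
  distribution with n - p_design df because per-cohort n is only ~150.
  Dosages enter unstandardized, so betas are per-allele. VIFs use the
  standard 1/(1 - R^2_j) definition and are computed exactly for every
  per-SNP fit via a Schur-complement rank-one update of the covariate Gram
  inverse; a metabolite whose covariate-only block violates the bound (50) is
  excluded wholesale. The MAF filter is inclusive (maf <= 0.05 removed) and
  uses minor-allele frequency. lambda_GC = median(chi^2_obs) / 0.45494.
* **QC.** All missingness thresholds are inclusive (>=). IQR uses linear
  interpolation between order statistics (the common quantile default; no
  convention was prescribed). The zero-IQR filter runs on the full input
  matrix at initial processing; the >= 50 % re-check uses per-cohort
  denominators. Metabolites with < 2 observed values count as zero-IQR.
  Xenobiotic cells left missing after imputation are handled complete-case
  per metabolite downstream.
* **Meta-analysis.** Fixed-effect only (the standard-error weighting scheme);
  replication requires p below 0.05 / |discovery set| and, by default, sign
  concordance with discovery (configurable — the concordance requirement is a
  design choice, not a prescribed rule).
* **Penalized solver.** Cyclic coordinate descent on the profiled problem:
  the unpenalized intercept + covariate block is residualized out of y and
  the standardized SNP columns, which is an exact reformulation, not an
  approximation. Convergence tolerance 1e-7 on the maximum coefficient
  change; SNP weights are back-transformed to per-dosage units. The grid is
  lambda in 10^(-5, -4.5, ..., 0) (11 values) x alpha in 0, 0.1, ..., 1
  (11 values); the penalty is (1/2n)||y - Xb||^2 +
  lambda(alpha||b||_1 + (1-alpha)/2 ||b||_2^2).
* **Cross-validation.** Fourfold, seeded, stratified by cohort (keeps batch
  composition balanced across folds; the stratification itself is a design
  choice). PCs are computed once on the combined dataset and reused across
  folds. Fold models never see held-out samples at any stage (fold-GWAS,
  clumping, fitting); an out-of-fold Pearson r is defined as 0 when a
  prediction is constant. Ties in mean r are broken by fewer mean SNPs, then
  by stronger penalty (parsimony). The winner is refit on all samples.
  Predictive R^2 is the square of the mean out-of-fold r, with the sign of r
  tracked separately; the inclusion filter is r > 0 AND R^2 > 0.025.
* **Clumping.** Greedy: smallest p becomes an index SNP, neighbours within
  1000 kb at r^2 >= 0.1 are removed; candidates require p < 0.01 (strict).
  Panel r^2 is the squared sample correlation of dosages; a monomorphic panel
  column counts as linked.
* **Association.** Ridge stabilization uses (R + eps I)/(1 + eps) with
  eps = 0.1 for the variance term — dividing by (1 + eps) keeps unit diagonal
  so a single-SNP model reduces exactly to that SNP's z — and Sigma_oo +
  eps I for z-score imputation (the imputation tool convention). Weights are
  standardized by LD-panel dosage sd (portable across users who lack the
  training genotypes; training-sample sd would be the alternative).
  Covariate coefficients stored with a model are ignored at association
  time. z-only summary statistics are converted by
  se = 1/sqrt(2 f (1-f)(n + z^2)), beta = z * se. Storey's pi0 uses a fixed
  lambda = 0.5 (no smoother; negligible difference at these list sizes), BH
  is the fully deterministic alternative.
* **MR.** Wald se is first-order (se_Y / |beta_X|), ignoring exposure error.
  IVW uses multiplicative random effects (se scaled by residual dispersion
  when > 1) and a normal p. Egger orients instruments to non-negative
  exposure betas, floors the dispersion at 1, and uses t with k - 2 df for
  both slope and intercept — with the small instrument counts typical here a
  normal reference would be anticonservative for the pleiotropy test.
  Weighted median weights are inverse second-order delta-method variances of
  the per-instrument ratios, with linear interpolation at cumulative weight
  0.5 and a seeded parametric bootstrap (default 1000 resamples) for the se.
* **Pipeline.** A single global seed fans out per stage through
  `SeedSequence([seed, stage_index])`, so toggling stages never changes
  another stage's stream; the manifest hashes every output file.

## Problem sizes

The simulation studies in `mwas.validation` (used by the test suite and
`scripts/acceptance.py`) run at desk scale: null lambda_GC pools 3 independent
studies x 4 metabolites x 2000 SNPs at n = 600 (a single metabolite's
lambda under block-LD has sd ~0.1 from ~200 independent loci, so a pooled
median is reported); the null association study uses 500 replicate phenotype
GWAS over one trained model; sign recovery runs 50 full train-plus-test
replicates at training n = 600 with 200 SNPs and phenotype n = 20 000; MR
studies use 20-21 instruments with 100-200 replicates. These sizes make the
Monte-Carlo error comfortably smaller than each check's tolerance while the
whole suite stays interactive.

## Known limitations

* Model-selection optimism: MR instruments come from models selected for
  predictive performance (winner's curse); no correction is applied.
* The weighted-score test assumes the LD panel matches the phenotype GWAS
  population; mismatch miscalibrates both imputation and the variance term.
* Hard-call genotypes only; dosage uncertainty and imputation quality (R^2)
  are not modelled.
* Fixed-effect meta-analysis assumes a common per-SNP effect across cohorts;
  only an optional dispersion diagnostic would flag heterogeneity, and none
  is computed by default.
* The PGS route follows the clumping + thresholding procedure defined here;
  exact concordance with any external PGS tool's defaults is not claimed.
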