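"""Simulation-based calibration and recovery studies.

These functions run the pipeline on synthetic studies with known ground truth
and summarize how well each stage behaves: genomic-inflation calibration under
the null, uniformity of weighted-score association p-values when no
metabolite-phenotype effect exists, sign recovery of a planted effect through
the whole train-then-test path, and the sampling behaviour of the MR
estimators.  They are used by the test suite and the reproduction script; all
randomness flows from explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .associate import badgers_association, harmonize_sumstats
from .gwas import compute_principal_components, genomic_inflation, run_gwas
from .mr import MRInput
from .qc import run_qc
from .simulate import (SimConfig, simulate_phenotype_sumstats, simulate_study)
from .train import cross_validate_and_select, prepare_training_genotypes

__all__ = [
    "null_lambda_gc",
    "train_planted_model",
    "badgers_null_pvalues",
    "badgers_sign_recovery",
    "simulate_mr_summary",
    "mqtl_recovery",
]

_NO_MISSING = {"nonxeno": 0.0, "xeno": 0.0}


def null_lambda_gc(seed: int = 0, n_studies: int = 3, n_samples: int = 600,
                   n_snps: int = 2000, n_metabolites: int = 4,
                   pcs: int = 5) -> float:
    """Pooled genomic inflation factor for GWAS of non-heritable metabolites.

    Metabolites are simulated with h2 = 0 (pure noise on the log10 scale), so
    every SNP test is null and a calibrated engine gives lambda ~ 1.  The
    median chi-square is pooled over ``n_studies`` independent study draws x
    ``n_metabolites`` each: a single metabolite's lambda is noisy under
    block-LD genotypes (few hundred independent loci), whereas the pooled
    estimate concentrates tightly around 1.
    """
    pvals = []
    for s in range(n_studies):
        sub = int(np.random.SeedSequence([int(seed), 11, s])
                  .generate_state(1)[0] % (2**31))
        cfg = SimConfig(n_samples_per_cohort=n_samples // 2, n_snps=n_snps,
                        n_metabolites=n_metabolites, h2_per_metabolite=0.0,
                        xenobiotic_fraction=0.0, missingness_rates=_NO_MISSING,
                        seed=sub)
        study = simulate_study(cfg, affected_metabolite=None)
        g = study.genotypes
        pc, _ = compute_principal_components(g, pcs)
        cov = study.covariates.join(pc)
        for met in study.metabolites.values.columns:
            y = np.log10(study.metabolites.values[met])
            res = run_gwas(g, y, cov)
            pvals.append(res["p"])
    return genomic_inflation(pd.concat(pvals))


def _study_config(seed: int, n_per_cohort: int, n_snps: int, h2: float,
                  pheno_n: int, effect: float) -> SimConfig:
    return SimConfig(n_samples_per_cohort=n_per_cohort, n_snps=n_snps,
                     n_metabolites=1, h2_per_metabolite=h2, n_causal_snps=1,
                     xenobiotic_fraction=0.0, seed=seed,
                     phenotype_gwas_n=pheno_n, phenotype_effect=effect)


def train_planted_model(seed: int = 0, n_per_cohort: int = 300,
                        n_snps: int = 200, h2: float = 0.3,
                        pheno_n: int = 20_000, effect: float = 0.5):
    """QC + fourfold-CV training of the single planted-mQTL metabolite.

    Returns ``(study, selection)`` where ``selection.best_model`` carries the
    final SNP weights and cross-validation performance.
    """
    cfg = _study_config(seed, n_per_cohort, n_snps, h2, pheno_n, effect)
    study = simulate_study(cfg)
    cleaned, _ = run_qc(study.metabolites)
    g = prepare_training_genotypes(study.genotypes)
    g = g.subset_samples(cleaned.cohort.index)
    pcs, _ = compute_principal_components(g, 5)
    cov = study.covariates.loc[g.sample_ids].join(pcs)
    sel = cross_validate_and_select(
        cleaned.values["met0001"], g, cov, cleaned.cohort,
        seed=seed, metabolite_id="met0001")
    return study, sel


def badgers_null_pvalues(n_replicates: int = 500, seed: int = 0,
                         n_per_cohort: int = 300, n_snps: int = 100,
                         pheno_n: int = 2000) -> np.ndarray:
    """Association p-values across replicate null phenotype GWAS.

    One heritable metabolite model is trained once; the phenotype summary
    statistics are then re-simulated ``n_replicates`` times with the planted
    metabolite -> phenotype effect set to zero.  Under the null the returned
    p-values are uniform on (0, 1).
    """
    study, sel = train_planted_model(seed=seed, n_per_cohort=n_per_cohort,
                                     n_snps=n_snps, effect=0.0)
    model = sel.best_model
    study.truth.metabolite_phenotype_effect[("met0001", "pheno1")] = 0.0
    study.truth.phenotype_gwas_n = pheno_n
    root = np.random.SeedSequence([int(seed), 99])
    pvals = np.empty(n_replicates)
    for r, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        ss = simulate_phenotype_sumstats(study.genotypes, study.truth,
                                         study.config, rng=rng)
        h = harmonize_sumstats(model, ss)
        res = badgers_association(model, h, study.genotypes,
                                  phenotype_id="pheno1")
        pvals[r] = res.p
    return pvals


def badgers_sign_recovery(n_replicates: int = 50, seed: int = 0,
                          n_per_cohort: int = 300, n_snps: int = 200,
                          h2: float = 0.3, pheno_n: int = 20_000,
                          effect: float = 0.5) -> tuple[float, np.ndarray]:
    """End-to-end sign recovery of a planted metabolite -> phenotype effect.

    Each replicate simulates a fresh study, trains the metabolite model
    through the full fourfold-CV path, simulates phenotype GWAS summary
    statistics under the planted effect, and records the weighted-score Z.
    Returns (fraction of replicates whose Z has the planted sign, all Z).
    """
    zs = np.empty(n_replicates)
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([int(seed), 7, r])
                       .generate_state(1)[0] % (2**31))
        study, sel = train_planted_model(seed=rep_seed,
                                         n_per_cohort=n_per_cohort,
                                         n_snps=n_snps, h2=h2,
                                         pheno_n=pheno_n, effect=effect)
        rng = np.random.default_rng(np.random.SeedSequence([rep_seed, 4]))
        ss = simulate_phenotype_sumstats(study.genotypes, study.truth,
                                         study.config, rng=rng)
        h = harmonize_sumstats(sel.best_model, ss)
        res = badgers_association(sel.best_model, h, study.genotypes,
                                  phenotype_id="pheno1")
        zs[r] = res.z_score
    frac = float(np.mean(np.sign(zs) == np.sign(effect)))
    return frac, zs


def mqtl_recovery(seed: int = 0, n: int = 2000, h2: float = 0.3,
                  ) -> tuple[float, float, float]:
    """OLS recovery of the planted per-allele mQTL effect.

    Simulates ``n`` samples with one causal SNP and no missingness and
    regresses the log10 metabolite on the causal dosage.  Returns
    (planted beta, estimated beta, se).
    """
    cfg = SimConfig(n_samples_per_cohort=n // 2, n_snps=100, n_metabolites=1,
                    h2_per_metabolite=h2, n_causal_snps=1,
                    xenobiotic_fraction=0.0, missingness_rates=_NO_MISSING,
                    seed=seed)
    study = simulate_study(cfg, affected_metabolite=None)
    snp, beta = study.truth.causal_snps_per_metabolite["met0001"][0]
    y = np.log10(study.metabolites.values["met0001"]).to_numpy()
    j = study.genotypes.snp_ids.get_loc(snp)
    x = study.genotypes.dosages[:, j]
    xc = x - x.mean()
    bhat = float(xc @ (y - y.mean()) / (xc @ xc))
    resid = (y - y.mean()) - bhat * xc
    se = float(np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc)))
    return float(beta), bhat, se


def simulate_mr_summary(seed: int, k: int = 20, true_effect: float = 0.3,
                        pleiotropy: float = 0.0, n_pleiotropic: int = 0,
                        se_exposure: float = 0.02, se_outcome: float = 0.05,
                        ) -> MRInput:
    """Summary-level two-sample MR dataset with optional directional pleiotropy.

    Instrument effects on the exposure are uniform on (0.2, 0.6); the first
    ``n_pleiotropic`` instruments add ``pleiotropy`` directly to the outcome
    (a direct path independent of instrument strength, satisfying the InSIDE
    condition).
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.2, 0.6, size=k)
    alpha = np.zeros(k)
    alpha[:n_pleiotropic] = pleiotropy
    bx = gamma + rng.normal(0.0, se_exposure, size=k)
    by = true_effect * gamma + alpha + rng.normal(0.0, se_outcome, size=k)
    return MRInput(bx, np.full(k, se_exposure), by, np.full(k, se_outcome))
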