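"""Synthetic study generator with planted ground truth.

Emulates the structure of a two-cohort CSF metabolomics study: LD-blocked
common genotypes, metabolites with sparse genetic architecture on the log10
scale, xenobiotic / non-xenobiotic missingness patterns, simple covariates
(age, sex, batch), and downstream-phenotype GWAS summary statistics generated
under a planted metabolite -> phenotype effect.  Every output is a pure
function of the configuration and its seed, so each downstream pipeline stage
can be tested against stored truth without external data.

Genotypes come from a Gaussian copula: one latent standard normal per SNP,
AR(1)-correlated within an LD block, thresholded at the Hardy-Weinberg
genotype frequencies.  Thresholding attenuates correlation, so the latent
correlation of each adjacent pair is *calibrated* (bivariate-normal orthant
probabilities, solved by bisection) to make the realized genotype correlation
equal ``ld_rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import owens_t, ndtr, ndtri

from .types import GenotypeMatrix, MetaboliteMatrix, SUMSTAT_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "SnpPanel",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_metabolome",
    "simulate_phenotype_sumstats",
    "simulate_study",
]

# Non-ambiguous allele pairs only: strand-palindromic SNPs (A/T, C/G) are
# removed during harmonization, so the generator does not plant any.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_BP_WITHIN_BLOCK = 10_000       # adjacent-SNP spacing; a 10-SNP block spans 90 kb
_BP_BETWEEN_BLOCKS = 2_000_000  # > the 1000-kb clumping window
_BLOCKS_PER_CHROM = 50


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror a desk-scale version of a two-cohort CSF study:
    ~150 samples per cohort, common SNPs (MAF >= 0.05) in 10-SNP LD blocks,
    mostly sparse single-mQTL metabolites, and moderate below-detection
    missingness for non-xenobiotics versus whole-sample absence for
    xenobiotics.
    """

    n_samples_per_cohort: int = 150
    n_snps: int = 1000
    n_metabolites: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    h2_per_metabolite: float = 0.3
    n_causal_snps: int = 1
    xenobiotic_fraction: float = 0.15
    missingness_rates: dict = field(
        default_factory=lambda: {"nonxeno": 0.05, "xeno": 0.40})
    seed: int = 0
    # Downstream-phenotype GWAS conditions.
    phenotype_gwas_n: int = 20_000
    phenotype_effect: float = 0.5
    # Nuisance effect sizes on log10 metabolite levels.
    age_effect: float = 0.05
    sex_effect: float = 0.05
    batch_shift: float = 0.10

    def __post_init__(self) -> None:
        if min(self.n_samples_per_cohort, self.n_snps, self.n_metabolites) <= 0:
            raise ConfigurationError("sample, SNP and metabolite counts must be positive")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within [0.05, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.h2_per_metabolite < 1.0:
            raise ConfigurationError("h2_per_metabolite must be in [0, 1)")
        if self.ld_block_size <= 0 or self.n_snps % self.ld_block_size != 0:
            raise ConfigurationError("ld_block_size must evenly partition n_snps")
        if not 0.0 <= self.xenobiotic_fraction <= 1.0:
            raise ConfigurationError("xenobiotic_fraction must be in [0, 1]")
        if self.n_causal_snps < 0 or self.n_causal_snps > self.n_snps:
            raise ConfigurationError("n_causal_snps out of range")


@dataclass
class SimTruth:
    """Planted ground truth recorded by the generator.

    ``causal_snps_per_metabolite`` maps a metabolite id to its list of
    (snp_id, per-allele effect on the log10 level); ``metabolite_phenotype_effect``
    maps (metabolite_id, phenotype_id) to the planted signed effect of the
    metabolite's genetic score on the downstream phenotype.
    """

    causal_snps_per_metabolite: dict
    metabolite_phenotype_effect: dict = field(default_factory=dict)
    phenotype_gwas_n: int = 0

    def to_jsonable(self) -> dict:
        return {
            "causal_snps_per_metabolite": {
                m: [[s, float(b)] for s, b in v]
                for m, v in self.causal_snps_per_metabolite.items()
            },
            "metabolite_phenotype_effect": {
                f"{m}::{p}": float(e)
                for (m, p), e in self.metabolite_phenotype_effect.items()
            },
            "phenotype_gwas_n": int(self.phenotype_gwas_n),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SimTruth":
        eff = {}
        for key, e in d.get("metabolite_phenotype_effect", {}).items():
            m, p = key.split("::")
            eff[(m, p)] = float(e)
        return cls(
            causal_snps_per_metabolite={
                m: [(s, float(b)) for s, b in v]
                for m, v in d["causal_snps_per_metabolite"].items()
            },
            metabolite_phenotype_effect=eff,
            phenotype_gwas_n=int(d.get("phenotype_gwas_n", 0)),
        )


def _bvn_sf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 > h, Z2 > k) for standard bivariate normals with correlation rho.

    Upper orthant probability via Owen's T.  Arguments broadcast; values of
    |h| or |k| below 1e-10 are nudged to keep the T-function arguments finite
    (error well below calibration tolerance).
    """
    h = np.where(np.abs(h) < 1e-10, 1e-10, np.asarray(h, dtype=float))
    k = np.where(np.abs(k) < 1e-10, 1e-10, np.asarray(k, dtype=float))
    rho = np.clip(np.asarray(rho, dtype=float), -0.99999, 0.99999)
    denom = np.sqrt(1.0 - rho**2)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    cdf = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    # Survival via inclusion-exclusion.
    return 1.0 - ndtr(h) - ndtr(k) + cdf


def _hwe_thresholds(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-normal cutpoints giving Hardy-Weinberg genotype frequencies."""
    maf = np.asarray(maf, dtype=float)
    t_het = ndtri((1.0 - maf) ** 2)   # above: dosage >= 1
    t_hom = ndtri(1.0 - maf**2)       # above: dosage == 2
    return t_het, t_hom


def _genotype_correlation(p1, p2, rho_latent) -> np.ndarray:
    """Population correlation of thresholded dosages for latent corr rho."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    t1a, t1b = _hwe_thresholds(p1)
    t2a, t2b = _hwe_thresholds(p2)
    e12 = (_bvn_sf(t1a, t2a, rho_latent) + _bvn_sf(t1a, t2b, rho_latent)
           + _bvn_sf(t1b, t2a, rho_latent) + _bvn_sf(t1b, t2b, rho_latent))
    cov = e12 - 4.0 * p1 * p2
    denom = 2.0 * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return cov / denom


def _calibrate_latent_rho(p1: np.ndarray, p2: np.ndarray, target: float,
                          n_iter: int = 60) -> np.ndarray:
    """Latent correlation giving genotype correlation ``target`` (bisection).

    Monotone in rho; capped at 0.9999 when the target is unattainable for the
    given MAF pair.
    """
    if target <= 0:
        return np.zeros(np.broadcast(p1, p2).shape)
    lo = np.zeros(np.broadcast(p1, p2).shape)
    hi = np.full_like(lo, 0.9999)
    reachable = _genotype_correlation(p1, p2, hi) >= target
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = _genotype_correlation(p1, p2, mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(reachable, out, 0.9999)


@dataclass
class SnpPanel:
    """Frozen SNP metadata plus the copula parameters needed to draw cohorts.

    ``latent_rho[j]`` links SNP ``j`` to SNP ``j - 1``; it is zero at block
    starts, so blocks are independent.
    """

    snp_meta: pd.DataFrame
    latent_rho: np.ndarray
    block_size: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an (n, n_snps) hard-call dosage matrix."""
        m = len(self.snp_meta)
        z = np.empty((n, m))
        eps = rng.standard_normal((n, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            r = self.latent_rho[j]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j]
        t_het, t_hom = _hwe_thresholds(self.snp_meta["maf"].to_numpy())
        return (z > t_het).astype(float) + (z > t_hom)

    def genotype_matrix(self, n: int, rng: np.random.Generator,
                        sample_prefix: str = "S") -> GenotypeMatrix:
        dos = self.sample(n, rng)
        ids = pd.Index([f"{sample_prefix}{i:05d}" for i in range(n)])
        gm = GenotypeMatrix(dos, self.snp_meta.copy(), ids)
        gm.panel = self  # keeps the copula available for fresh cohorts
        return gm


def build_snp_panel(config: SimConfig) -> SnpPanel:
    """Draw SNP metadata and calibrate the within-block latent correlations."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    m, b = config.n_snps, config.ld_block_size
    n_blocks = m // b
    # One MAF per LD block: strong dosage correlation between two SNPs is
    # only attainable when their allele frequencies match (r^2 = 1 forces
    # equality), as in real haplotype blocks.
    maf = np.repeat(
        rng.uniform(config.maf_range[0], config.maf_range[1], size=n_blocks), b)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    chrom = np.repeat(np.arange(n_blocks) // _BLOCKS_PER_CHROM + 1, b)
    block_of = np.repeat(np.arange(n_blocks), b)
    within = np.tile(np.arange(b), n_blocks)
    block_in_chrom = np.repeat(np.arange(n_blocks) % _BLOCKS_PER_CHROM, b)
    bp = 1 + block_in_chrom * _BP_BETWEEN_BLOCKS + within * _BP_WITHIN_BLOCK

    latent = np.zeros(m)
    inner = within > 0  # pairs (j-1, j) inside a block
    if config.ld_rho > 0 and inner.any():
        latent[inner] = _calibrate_latent_rho(
            maf[np.flatnonzero(inner) - 1], maf[inner], config.ld_rho)

    meta = pd.DataFrame({
        "snp": [f"rs{c}_{p}" for c, p in zip(chrom, bp)],
        "chr": chrom.astype(int),
        "bp": bp.astype(int),
        "effect_allele": a1,
        "other_allele": a2,
        "maf": maf,
        "block": block_of,
    })
    return SnpPanel(meta, latent, b)


def simulate_genotypes(config: SimConfig, n: int | None = None,
                       rng: np.random.Generator | None = None,
                       panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Generate hard-call dosages for ``n`` samples (default: both cohorts)."""
    panel = panel if panel is not None else build_snp_panel(config)
    if n is None:
        n = 2 * config.n_samples_per_cohort
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    gm = panel.genotype_matrix(n, rng)
    return gm


def _cohort_labels(config: SimConfig, sample_ids: pd.Index) -> pd.Series:
    n = len(sample_ids)
    half = n // 2
    labels = np.array(["A"] * half + ["B"] * (n - half))
    return pd.Series(labels, index=sample_ids, name="cohort")


def simulate_covariates(config: SimConfig, sample_ids: pd.Index,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Age at draw (years), sex code (0/1) and batch (= cohort) per sample."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    n = len(sample_ids)
    cohort = _cohort_labels(config, sample_ids)
    return pd.DataFrame({
        "age_at_draw": np.round(rng.normal(65.0, 8.0, size=n), 1),
        "sex": rng.integers(0, 2, size=n),
        "batch": cohort.to_numpy(),
    }, index=sample_ids)


def simulate_metabolome(genotypes: GenotypeMatrix, config: SimConfig,
                        covariates: pd.DataFrame | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[MetaboliteMatrix, SimTruth]:
    """Metabolite abundances with planted genetic effects and missingness.

    Each metabolite's log10 level is a scaled genetic score (sample variance
    exactly ``h2``) plus small covariate effects, a cohort batch shift, and
    Gaussian noise of variance ``1 - h2``; abundances are ``10 ** log10``.
    Non-xenobiotics are left-censored below a per-metabolite detection
    quantile; xenobiotics go missing in whole samples at random.
    """
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise ConfigurationError("genotype matrix must be non-empty")
    if config.h2_per_metabolite >= 1.0:
        raise ConfigurationError("heritability must be < 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    n, m_snp = genotypes.dosages.shape
    ids = genotypes.sample_ids
    if covariates is None:
        covariates = simulate_covariates(config, ids, rng=rng)
    cohort = pd.Series(covariates["batch"].to_numpy(), index=ids, name="cohort")

    age_z = (covariates["age_at_draw"].to_numpy() - 65.0) / 8.0
    sex = covariates["sex"].to_numpy().astype(float)
    batch = (cohort.to_numpy() == "B").astype(float)
    nuisance = (config.age_effect * age_z + config.sex_effect * sex
                + config.batch_shift * batch)

    h2 = config.h2_per_metabolite
    names = [f"met{j + 1:04d}" for j in range(config.n_metabolites)]
    n_xeno = int(round(config.xenobiotic_fraction * config.n_metabolites))
    xeno_idx = rng.choice(config.n_metabolites, size=n_xeno, replace=False)
    xeno = np.zeros(config.n_metabolites, dtype=bool)
    xeno[xeno_idx] = True

    log_values = np.empty((n, config.n_metabolites))
    causal: dict = {}
    snp_ids = genotypes.snp_meta["snp"].to_numpy()
    for j, name in enumerate(names):
        effects: list = []
        score = np.zeros(n)
        if h2 > 0 and config.n_causal_snps > 0:
            chosen = rng.choice(m_snp, size=config.n_causal_snps, replace=False)
            raw = rng.standard_normal(config.n_causal_snps)
            score = genotypes.dosages[:, chosen] @ raw
            sd = score.std()
            if sd > 0:
                scale = np.sqrt(h2) / sd
            else:  # degenerate draw (monomorphic set): no genetic signal
                scale = 0.0
            score = score * scale
            score = score - score.mean()
            effects = [(snp_ids[c], float(raw[i] * scale))
                       for i, c in enumerate(chosen)]
        noise = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
        log_values[:, j] = score + nuisance + noise
        causal[name] = effects

    values = pd.DataFrame(10.0 ** log_values, index=ids, columns=names)

    # Missingness injection.
    rate_nx = float(config.missingness_rates.get("nonxeno", 0.0))
    rate_x = float(config.missingness_rates.get("xeno", 0.0))
    for j, name in enumerate(names):
        col = values[name].to_numpy()
        if xeno[j]:
            if rate_x > 0:
                mask = rng.random(n) < rate_x
                col[mask] = np.nan
        elif rate_nx > 0:  # left-censoring below the detection quantile
            cut = np.quantile(col, rate_nx)
            col[col < cut] = np.nan
        values[name] = col

    mm = MetaboliteMatrix(values, pd.Series(xeno, index=names), cohort)
    truth = SimTruth(causal_snps_per_metabolite=causal,
                     phenotype_gwas_n=config.phenotype_gwas_n)
    return mm, truth


def _marginal_gwas(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized simple-regression sumstats of y on each SNP."""
    n = len(y)
    gc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, t, p


def simulate_phenotype_sumstats(genotypes: GenotypeMatrix, truth: SimTruth,
                                config: SimConfig,
                                phenotype_id: str = "pheno1",
                                rng: np.random.Generator | None = None,
                                ) -> pd.DataFrame:
    """GWAS summary statistics for a downstream phenotype.

    The phenotype is simulated on a *fresh* cohort of ``phenotype_gwas_n``
    individuals drawn from the same SNP panel as ``effect x (true genetic
    score of each affected metabolite) + N(0, 1)`` noise, then per-SNP
    marginal regressions are emitted for every panel SNP.
    """
    n = truth.phenotype_gwas_n or config.phenotype_gwas_n
    if n < 50:
        raise ConfigurationError("phenotype GWAS n < 50: se estimates unstable")
    effects = {m: e for (m, p), e in truth.metabolite_phenotype_effect.items()
               if p == phenotype_id}
    if not effects:
        raise ConfigurationError(
            f"truth carries no metabolite effect for phenotype {phenotype_id!r}")
    panel: SnpPanel = getattr(genotypes, "panel", None)
    if panel is None:
        raise ConfigurationError("genotype matrix lacks its simulation panel")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))

    dosages = panel.sample(n, rng)
    snp_pos = {s: i for i, s in enumerate(panel.snp_meta["snp"])}
    y = rng.standard_normal(n)
    for met, eff in effects.items():
        if eff == 0:
            continue
        beta_vec = np.zeros(dosages.shape[1])
        for snp_id, b in truth.causal_snps_per_metabolite.get(met, []):
            beta_vec[snp_pos[snp_id]] = b
        y = y + eff * (dosages @ beta_vec)

    beta, se, t, p = _marginal_gwas(dosages, y)
    meta = panel.snp_meta
    out = pd.DataFrame({
        "snp": meta["snp"], "chr": meta["chr"], "bp": meta["bp"],
        "effect_allele": meta["effect_allele"],
        "other_allele": meta["other_allele"],
        "beta": beta, "se": se, "stat": t, "p": p,
        "n": n,
    })
    return out[SUMSTAT_COLUMNS]


@dataclass
class SimStudy:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    panel: SnpPanel
    genotypes: GenotypeMatrix
    metabolites: MetaboliteMatrix
    covariates: pd.DataFrame
    truth: SimTruth

    @property
    def cohort(self) -> pd.Series:
        return self.metabolites.cohort


def simulate_study(config: SimConfig,
                   affected_metabolite: str | None = "met0001",
                   phenotype_id: str = "pheno1") -> SimStudy:
    """Generate genotypes, covariates and metabolome for both cohorts.

    Plants ``config.phenotype_effect`` of ``affected_metabolite``'s genetic
    score on ``phenotype_id`` in the returned truth (pass ``None`` to plant
    nothing), ready for :func:`simulate_phenotype_sumstats`.
    """
    panel = build_snp_panel(config)
    rng_g = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    genotypes = panel.genotype_matrix(2 * config.n_samples_per_cohort, rng_g)
    covariates = simulate_covariates(config, genotypes.sample_ids)
    metabolites, truth = simulate_metabolome(genotypes, config,
                                             covariates=covariates)
    if affected_metabolite is not None:
        truth.metabolite_phenotype_effect[(affected_metabolite, phenotype_id)] = \
            config.phenotype_effect
    return SimStudy(config, panel, genotypes, metabolites, covariates, truth)
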