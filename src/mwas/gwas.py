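"""Per-metabolite additive-model GWAS with covariates.

Each SNP is tested by OLS of the (log10) metabolite on [1, dosage, covariates]
with exact two-sided p-values from the t distribution (cohort sizes here are
small, ~150, so the normal approximation is not used).  The per-SNP fits are
computed via Frisch-Waugh-Lovell residualization, which is algebraically
identical to the full joint OLS but vectorizes over SNPs.  Variance inflation
factors are computed exactly for every design column of every per-SNP fit via
a Schur-complement rank-one update of the covariate Gram inverse, and any fit
with a VIF at or above the bound is suppressed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, SUMSTAT_COLUMNS

__all__ = [
    "build_design",
    "compute_principal_components",
    "run_gwas",
    "maf_filter",
    "snp_missingness_filter",
    "genomic_inflation",
    "bonferroni_threshold",
    "VifExceeded",
]

#: median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493642...


class VifExceeded(RuntimeError):
    """Covariate-only design already violates the VIF bound."""


def compute_principal_components(g: GenotypeMatrix, k: int,
                                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-``k`` PCs of the column-standardized dosage matrix.

    Constant SNP columns are dropped before standardization.  Sign convention:
    each loading vector's largest-|entry| element is positive, making scores
    deterministic.  Returns (scores indexed by sample, explained-variance
    fractions).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return pd.DataFrame(index=g.sample_ids), np.array([])
    if g.n_samples <= k:
        raise ValueError("need more samples than requested components")
    x = g.dosages
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(k, len(s))
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    scores = u[:, :k] * s[:k] * flip[:k]
    explained = (s**2 / (s**2).sum())[:k]
    cols = [f"pc{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=g.sample_ids, columns=cols), explained


def build_design(covariates: pd.DataFrame | None,
                 sample_ids: pd.Index) -> np.ndarray:
    """Numeric covariate block: categoricals one-hot expanded (first dropped).

    Degenerate (constant) columns are removed; the intercept is added by the
    regression itself.
    """
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((len(sample_ids), 0))
    cov = covariates.loc[sample_ids]
    if cov.isna().any().any():
        raise ValueError("covariates contain missing entries for analyzed samples")
    num = pd.get_dummies(cov, drop_first=True, dtype=float)
    arr = num.to_numpy(dtype=float)
    keep = arr.std(axis=0) > 0
    return arr[:, keep]


def _vif_per_snp(gc: np.ndarray, cc: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact VIFs for every per-SNP design [1, snp, covariates].

    ``gc``/``cc`` are the centered dosage and covariate blocks.  Returns
    (snp VIFs, covariate VIFs as (n_cov, n_snps), covariate-only VIFs).
    VIF_j = 1 / (1 - R^2_j) from regressing column j on the others; for the
    augmented design the covariate entries come from the Schur-complement
    update of the covariate Gram inverse.
    """
    n_snps = gc.shape[1]
    norm_g = (gc * gc).sum(axis=0)
    if cc.shape[1] == 0:
        snp_vif = np.where(norm_g > 0, 1.0, np.inf)
        return snp_vif, np.empty((0, n_snps)), np.array([])
    a = cc.T @ cc
    norm_c = np.diag(a)
    if np.linalg.matrix_rank(a) < a.shape[0]:
        # exact collinearity among covariates: every involved VIF is infinite
        base_vif = np.full(cc.shape[1], np.inf)
        snp_vif = np.full(n_snps, np.inf)
        return snp_vif, np.full((cc.shape[1], n_snps), np.inf), base_vif
    a_inv = np.linalg.inv(a)
    base_vif = np.diag(a_inv) * norm_c  # covariate-only design

    ctg = cc.T @ gc                      # (n_cov, n_snps)
    u = a_inv @ ctg
    s = norm_g - np.einsum("ij,ij->j", ctg, u)  # residual SS of each SNP on C
    s = np.maximum(s, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snp_vif = np.where(s > 0, norm_g / s, np.inf)
        cov_vif = (np.diag(a_inv)[:, None] + u**2 / s) * norm_c[:, None]
        cov_vif = np.where(s > 0, cov_vif, np.inf)
    return snp_vif, cov_vif, base_vif


def run_gwas(g: GenotypeMatrix, y: pd.Series, covariates: pd.DataFrame | None,
             vif_max: float = 50.0) -> pd.DataFrame:
    """Additive-model GWAS of one metabolite.

    ``y`` may contain missing values; the fit is complete-case.  Per SNP, OLS
    of y on [1, dosage, covariates] with two-sided p from t(n - p_design).
    Monomorphic SNPs and SNPs whose fit has any design-column VIF >=
    ``vif_max`` yield missing beta/se/p with a ``reason`` code.  Raises
    :class:`VifExceeded` when the covariate-only block already violates the
    bound (the metabolite is excluded wholesale).
    """
    y = y.reindex(g.sample_ids)
    used = y.notna().to_numpy()
    n = int(used.sum())
    dos = g.dosages[used]
    yv = y.to_numpy(dtype=float)[used]
    cov = build_design(covariates, g.sample_ids[used])
    p_design = 2 + cov.shape[1]  # intercept + snp + covariates
    if n <= p_design:
        raise ValueError(f"too few complete cases (n={n}) for the design")

    gc = dos - dos.mean(axis=0)
    cc = cov - cov.mean(axis=0)
    snp_vif, cov_vif, base_vif = _vif_per_snp(gc, cc)
    if len(base_vif) and np.nanmax(base_vif) >= vif_max:
        raise VifExceeded(
            f"covariate-only VIF {np.nanmax(base_vif):.1f} >= {vif_max}")

    # Residualize y and each SNP on [1, covariates] (Frisch-Waugh-Lovell).
    yc = yv - yv.mean()
    if cc.shape[1]:
        coef_y, *_ = np.linalg.lstsq(cc, yc, rcond=None)
        y_res = yc - cc @ coef_y
        coef_g, *_ = np.linalg.lstsq(cc, gc, rcond=None)
        g_res = gc - cc @ coef_g
    else:
        y_res, g_res = yc, gc

    sxx = (g_res * g_res).sum(axis=0)
    sxy = g_res.T @ y_res
    syy = float(y_res @ y_res)
    df = n - p_design
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / df / sxx)
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=df)

    mono = gc.std(axis=0) == 0
    vif_bad = snp_vif >= vif_max
    if cov_vif.size:
        vif_bad |= (cov_vif >= vif_max).any(axis=0)
    invalid = mono | vif_bad | ~np.isfinite(se) | (se <= 0)
    reason = np.where(mono, "monomorphic", np.where(vif_bad, "vif", ""))
    beta[invalid] = np.nan
    se[invalid] = np.nan
    t[invalid] = np.nan
    pvals[invalid] = np.nan

    meta = g.snp_meta
    out = pd.DataFrame({
        "snp": meta["snp"].to_numpy(), "chr": meta["chr"].to_numpy(),
        "bp": meta["bp"].to_numpy(),
        "effect_allele": meta["effect_allele"].to_numpy(),
        "other_allele": meta["other_allele"].to_numpy(),
        "beta": beta, "se": se, "stat": t, "p": pvals, "n": n,
    })
    out["maf"] = meta["maf"].to_numpy() if "maf" in meta else g.realized_maf()
    out["reason"] = reason
    return out[SUMSTAT_COLUMNS + ["maf", "reason"]]


def maf_filter(result: pd.DataFrame, cut: float = 0.05) -> pd.DataFrame:
    """Drop SNPs with minor-allele frequency <= ``cut`` (inclusive)."""
    if "maf" not in result:
        raise ValueError("result carries no 'maf' column")
    return result.loc[result["maf"].to_numpy() > cut].reset_index(drop=True)


def snp_missingness_filter(g: GenotypeMatrix, max_missing: float = 0.01,
                           ) -> GenotypeMatrix:
    """Pre-GWAS filter: remove SNPs with >= ``max_missing`` missing calls.

    Missing dosage calls are NaN; the synthetic generator emits none, so this
    is a pass-through there, but external genotype files may carry them.
    """
    frac = np.isnan(g.dosages).mean(axis=0)
    keep = frac < max_missing
    return GenotypeMatrix(g.dosages[:, keep],
                          g.snp_meta.loc[keep].reset_index(drop=True),
                          g.sample_ids)


def genomic_inflation(p: pd.Series | np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2(1) over its null median."""
    p = np.asarray(pd.Series(p).dropna(), dtype=float)
    if len(p) == 0:
        return float("nan")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bonferroni_threshold(base_alpha: float, n_tests: int) -> float:
    """Family-wise threshold ``base_alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests
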