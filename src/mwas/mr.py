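"""Two-sample Mendelian randomization estimators.

Instruments are independent (clumped) SNPs with harmonized exposure
(metabolite GWAS) and outcome (phenotype GWAS) effects.  Four estimators:

* Wald ratio — single instrument, first-order delta-method se.
* IVW — weighted regression of outcome on exposure betas through the origin,
  weights 1/se_outcome^2, with multiplicative random-effects scaling of the
  se when residual dispersion exceeds 1.
* Egger — weighted regression with an intercept; the intercept (and its
  p-value, t with k-2 df) is the directional-pleiotropy test, the slope the
  pleiotropy-adjusted causal estimate.  Instruments are oriented so exposure
  betas are non-negative.
* Weighted median — consistent while < 50% of instrument weight is
  pleiotropic; se from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MRResult

__all__ = ["MRInput", "wald_ratio", "ivw_mr", "egger_mr",
           "weighted_median_mr", "run_all_mr"]


@dataclass
class MRInput:
    """Harmonized instrument effects (common effect allele per SNP)."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    snp_ids: list | None = None

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        k = len(self.beta_exposure)
        if k == 0:
            raise ValueError("need at least one instrument")
        for arr in (self.se_exposure, self.beta_outcome, self.se_outcome):
            if len(arr) != k:
                raise ValueError("instrument arrays must have equal length")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.beta_exposure)


def wald_ratio(i: MRInput) -> MRResult:
    """Single-instrument causal estimate beta_Y / beta_X."""
    if i.n_instruments != 1:
        raise ValueError("Wald ratio requires exactly one instrument")
    bx, by, sy = i.beta_exposure[0], i.beta_outcome[0], i.se_outcome[0]
    if bx == 0:
        raise ValueError("weak/degenerate instrument: exposure beta is zero")
    est = by / bx
    se = sy / abs(bx)  # first-order delta method
    z = est / se
    return MRResult("wald_ratio", float(est), float(se),
                    float(2 * stats.norm.sf(abs(z))), 1)


def ivw_mr(i: MRInput, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate (regression through the origin).

    With one instrument this defers to the Wald ratio.  Multiplicative
    random effects scale the se by the residual standard deviation when it
    exceeds 1, mirroring the random-effects flavour of summary-data MR.
    """
    if i.n_instruments == 1:
        return ivw_single(i)
    bx, by, sy = i.beta_exposure, i.beta_outcome, i.se_outcome
    if np.all(bx == 0):
        raise ValueError("all exposure betas are zero")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by) / sxx)
    se = sxx ** -0.5
    k = i.n_instruments
    resid = by - est * bx
    dispersion = float(np.sum(w * resid**2) / (k - 1))
    if random_effects and dispersion > 1.0:
        se *= np.sqrt(dispersion)
    z = est / se
    return MRResult("ivw", est, float(se), float(2 * stats.norm.sf(abs(z))), k)


def ivw_single(i: MRInput) -> MRResult:
    r = wald_ratio(i)
    return MRResult("ivw", r.estimate, r.se, r.p, 1)


def egger_mr(i: MRInput) -> MRResult:
    """Egger regression: weighted fit of by on bx with an intercept.

    Requires >= 3 instruments; they are oriented so that every exposure beta
    is non-negative (the standard Egger orientation).  The intercept estimates
    average directional pleiotropy; its two-sided t-test (k - 2 df) is the
    pleiotropy test.  The se of both coefficients carries the multiplicative
    dispersion factor (floored at 1).
    """
    if i.n_instruments < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    flip = np.sign(i.beta_exposure)
    flip[flip == 0] = 1.0
    bx = i.beta_exposure * flip
    by = i.beta_outcome * flip
    sy = i.se_outcome
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    if np.linalg.matrix_rank(xtwx) < 2 or np.isclose(np.std(bx), 0.0):
        raise ValueError("exposure betas collinear with intercept: "
                         "Egger design is rank deficient")
    coef = np.linalg.solve(xtwx, xtw @ by)
    k = i.n_instruments
    resid = by - x @ coef
    dispersion = max(float(np.sum(w * resid**2) / (k - 2)), 1.0)
    cov = np.linalg.inv(xtwx) * dispersion
    se = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se[1]
    t_int = coef[0] / se[0]
    df = k - 2
    return MRResult(
        "egger", float(coef[1]), float(se[1]),
        float(2 * stats.t.sf(abs(t_slope), df=df)), k,
        egger_intercept=float(coef[0]), egger_intercept_se=float(se[0]),
        egger_intercept_p=float(2 * stats.t.sf(abs(t_int), df=df)))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median_mr(i: MRInput, n_boot: int = 1000,
                       seed: int = 0) -> MRResult:
    """Weighted median of the per-instrument Wald ratios.

    Weights are the inverse variance of each ratio (second-order delta
    method).  The se comes from a parametric bootstrap: ``n_boot`` resamples
    of the instrument betas from their normal sampling errors.
    """
    if i.n_instruments < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    bx, sx, by, sy = (i.beta_exposure, i.se_exposure,
                      i.beta_outcome, i.se_outcome)
    ratios = by / bx
    var = sy**2 / bx**2 + (by**2 * sx**2) / bx**4
    weights = 1.0 / var
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        r_b = by_b[ok] / bx_b[ok]
        v_b = sy[ok]**2 / bx_b[ok]**2 + (by_b[ok]**2 * sx[ok]**2) / bx_b[ok]**4
        boots[b] = _weighted_median(r_b, 1.0 / v_b)
    se = float(np.std(boots))
    z = est / se if se > 0 else np.inf
    return MRResult("weighted_median", est, se,
                    float(2 * stats.norm.sf(abs(z))), i.n_instruments)


def run_all_mr(i: MRInput, n_boot: int = 1000, seed: int = 0,
               ) -> pd.DataFrame:
    """All applicable estimators for one exposure-outcome pair.

    Single instrument: Wald ratio only.  Two instruments: IVW.  Three or
    more: IVW, Egger and weighted median.
    """
    results: list[MRResult] = []
    if i.n_instruments == 1:
        results.append(wald_ratio(i))
    else:
        results.append(ivw_mr(i))
        if i.n_instruments >= 3:
            try:
                results.append(egger_mr(i))
            except ValueError:
                pass
            results.append(weighted_median_mr(i, n_boot=n_boot, seed=seed))
    return pd.DataFrame([{
        "method": r.method, "estimate": r.estimate, "se": r.se, "p": r.p,
        "n_instruments": r.n_instruments,
        "egger_intercept": r.egger_intercept,
        "egger_intercept_p": r.egger_intercept_p,
    } for r in results])
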