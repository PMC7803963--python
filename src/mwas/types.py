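"""Core in-memory containers shared across the pipeline stages.

Genotypes are sample x SNP dosage matrices with per-SNP metadata; metabolite
abundances are sample x metabolite tables where ``NaN`` marks a missing
(below-detection or absent) measurement.  Per-SNP association results and
summary statistics travel as plain :class:`pandas.DataFrame` objects with the
column conventions documented in :mod:`mwas.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order for per-SNP association results (GWAS, meta-analysis).
SUMSTAT_COLUMNS = [
    "snp", "chr", "bp", "effect_allele", "other_allele",
    "beta", "se", "stat", "p", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(a: str) -> str:
    """Reverse-strand complement of a single-base allele."""
    try:
        return _COMPLEMENT[a.upper()]
    except KeyError:
        raise ValueError(f"cannot complement allele {a!r}") from None


def is_ambiguous_pair(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (palindromic) allele pairs: A/T and C/G."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class GenotypeMatrix:
    """Sample x SNP additive dosages in [0, 2] plus SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array; hard calls are {0, 1, 2}.
    snp_meta
        One row per SNP with columns ``snp, chr, bp, effect_allele,
        other_allele, maf``; ``maf`` is the minor-allele frequency
        (``min(f, 1 - f)`` of the effect allele frequency ``f``).
    sample_ids
        Sample identifiers, aligned to rows of ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = pd.Index(self.sample_ids)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_meta)} SNPs"
            )
        if not self.snp_meta["snp"].is_unique:
            raise ValueError("SNP identifiers must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snp_meta["snp"])

    def realized_maf(self) -> np.ndarray:
        """Minor-allele frequency observed in the dosage matrix."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (pd.Index, list)):
            idx = self.sample_ids.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown sample id in subset request")
        else:
            arr = np.asarray(mask_or_ids)
            idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return GenotypeMatrix(self.dosages[idx], self.snp_meta.copy(),
                              self.sample_ids[idx])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        pos = self.snp_ids.get_indexer(pd.Index(snp_ids))
        if (pos < 0).any():
            missing = pd.Index(snp_ids)[pos < 0]
            raise KeyError(f"SNPs absent from genotype matrix: {list(missing[:5])}")
        return GenotypeMatrix(
            self.dosages[:, pos],
            self.snp_meta.iloc[pos].reset_index(drop=True),
            self.sample_ids,
        )


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite relative abundances with a missingness mask.

    ``values`` holds median-scaled (unitless) abundances with ``NaN`` where a
    measurement is missing; ``xenobiotic`` flags compounds of external origin
    (diet, drugs) that may be genuinely absent from a sample and are therefore
    treated differently by the QC filters; ``cohort`` labels each sample's
    study cohort.
    """

    values: pd.DataFrame
    xenobiotic: pd.Series
    cohort: pd.Series

    def __post_init__(self) -> None:
        self.xenobiotic = self.xenobiotic.reindex(self.values.columns).astype(bool)
        self.cohort = self.cohort.reindex(self.values.index)
        if self.cohort.isna().any():
            raise ValueError("every sample needs a cohort label")
        if not self.values.columns.is_unique:
            raise ValueError("metabolite identifiers must be unique")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.values.copy(), self.xenobiotic.copy(),
                                self.cohort.copy())


@dataclass
class PredictionModel:
    """Per-metabolite genetic prediction model (the MWAS exchange object).

    ``weights`` maps SNPs to per-dosage-unit effects on the (log10) metabolite;
    ``family`` follows the mixing parameter: alpha = 1 is the lasso, alpha = 0
    ridge regression, anything between an elastic net; ``pgs`` models carry a
    GWAS p-value threshold instead of (alpha, lambda).  ``cv_mean_r`` is the
    mean out-of-fold Pearson correlation from fourfold cross-validation and
    ``cv_r2`` its square.
    """

    metabolite_id: str
    family: str
    weights: pd.DataFrame  # columns: snp, effect_allele, other_allele, weight
    alpha: float | None = None
    lam: float | None = None
    p_threshold: float | None = None
    covariate_coefficients: pd.Series | None = None
    intercept: float = 0.0
    cv_mean_r: float = float("nan")
    n_snps_mean: float = float("nan")

    @property
    def cv_r2(self) -> float:
        return float(self.cv_mean_r) ** 2

    @property
    def n_snps(self) -> int:
        return int((self.weights["weight"] != 0).sum())

    def passes_inclusion_filter(self, r2_min: float = 0.025) -> bool:
        """Positive out-of-fold correlation and predictive R^2 above ``r2_min``."""
        return bool(self.cv_mean_r > 0 and self.cv_r2 > r2_min)


@dataclass
class MRResult:
    """One Mendelian-randomization estimate.

    ``estimate`` is in outcome units per exposure unit; for Egger regression
    the intercept and its p-value form the directional-pleiotropy test.
    """

    method: str
    estimate: float
    se: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def summary(self) -> str:
        lines = [
            f"MR method:      {self.method}",
            f"instruments:    {self.n_instruments}",
            f"estimate (se):  {self.estimate:.6g} ({self.se:.6g})",
            f"p (two-sided):  {self.p:.3g}",
        ]
        if self.egger_intercept is not None:
            lines.append(
                f"Egger intercept: {self.egger_intercept:.6g} "
                f"(p = {self.egger_intercept_p:.3g})"
            )
        return "\n".join(lines)


@dataclass
class AssociationResult:
    """Metabolite-phenotype association from summary statistics."""

    metabolite_id: str
    phenotype_id: str
    z_score: float
    p: float
    n_snps_used: int
    q_value: float = float("nan")
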