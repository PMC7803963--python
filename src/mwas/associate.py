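"""Summary-statistic metabolite-phenotype association testing.

A trained prediction model (SNP weights for a genetically regulated metabolite
level) is combined with downstream-phenotype GWAS summary statistics in the
TWAS style: harmonize the phenotype statistics to the model's effect alleles,
optionally impute z-scores for model SNPs missing from the phenotype GWAS from
an LD reference panel (conditional-Gaussian / ImpG form), then test

    Z = (w~' z) / sqrt(w~' R w~),    w~_j = w_j * sd_j,

where ``z`` are the harmonized phenotype z-scores, ``sd_j`` the dosage
standard deviation of SNP j in the LD panel (putting the per-dosage weights on
the standardized-genotype scale) and ``R`` the panel SNP-SNP correlation
matrix, ridge-stabilized as ``(R + eps I) / (1 + eps)`` so it stays a
correlation matrix and a single-SNP model reduces exactly to that SNP's z.
Under the null of no metabolite-phenotype association, Z is standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (AssociationResult, GenotypeMatrix, PredictionModel,
                    complement_allele, is_ambiguous_pair)
from .meta import _orientation

__all__ = [
    "HarmonizedStats",
    "harmonize_sumstats",
    "impute_missing_zscores",
    "badgers_association",
    "compute_qvalues",
]


@dataclass
class HarmonizedStats:
    """Per-SNP phenotype statistics oriented to a model's effect alleles.

    ``table`` has one row per model SNP with columns snp, z, beta, se, n,
    provenance (as_is / sign_flipped / strand_complemented /
    strand_complemented+sign_flipped / imputed) and, for imputed entries, an
    imputation-quality r2.  ``dropped`` lists (snp, reason) pairs.
    """

    table: pd.DataFrame
    dropped: list


def _beta_from_z(z: np.ndarray, freq: np.ndarray, n: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Effect size and se implied by a z-score on a standardized-trait scale.

    Standard approximation: se = 1 / sqrt(2 f (1-f) (n + z^2)), beta = z * se.
    """
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * (n + z**2))
    return z * se, se


def harmonize_sumstats(model: PredictionModel, stats_df: pd.DataFrame,
                       ) -> HarmonizedStats:
    """Orient phenotype summary statistics to the model's effect alleles.

    Matching is by SNP id with a chr:bp fallback; swapped alleles flip the
    sign, strand complements are resolved by complementing, and ambiguous
    (A/T, C/G) SNPs are dropped.  ``or`` columns are converted via beta =
    ln(OR); z-only records get beta/se from the effect-allele frequency and
    sample size.  Model SNPs absent from the statistics are emitted with
    missing z (candidates for LD imputation).
    """
    st = stats_df.copy()
    st.columns = [c.lower() for c in st.columns]
    if "beta" not in st and "or" in st:
        st["beta"] = np.log(st["or"].astype(float))
    if "z" not in st:
        if "beta" in st and "se" in st:
            st["z"] = st["beta"].astype(float) / st["se"].astype(float)
        else:
            raise ValueError("summary statistics need beta+se, or, or z")
    if ("beta" not in st or "se" not in st) and "z" in st:
        if "eaf" not in st or "n" not in st:
            raise ValueError("z-only statistics need eaf and n for conversion")
        beta, se = _beta_from_z(st["z"].to_numpy(dtype=float),
                                st["eaf"].to_numpy(dtype=float),
                                st["n"].to_numpy(dtype=float))
        st["beta"], st["se"] = beta, se

    by_id = st.set_index(st["snp"].astype(str))
    by_pos = None
    if "chr" in st and "bp" in st:
        by_pos = st.set_index(st["chr"].astype(str) + ":" + st["bp"].astype(str))

    rows, dropped = [], []
    w = model.weights
    for _, m in w.iterrows():
        rec = None
        sid = str(m["snp"])
        if sid in by_id.index:
            rec = by_id.loc[sid]
        elif by_pos is not None and "chr" in w.columns and "bp" in w.columns:
            chrbp = f"{m['chr']}:{m['bp']}"
            if chrbp in by_pos.index:
                rec = by_pos.loc[chrbp]
        if rec is None:
            rows.append({"snp": sid, "z": np.nan, "beta": np.nan,
                         "se": np.nan, "n": np.nan, "provenance": "missing",
                         "impute_r2": np.nan})
            continue
        if isinstance(rec, pd.DataFrame):
            rec = rec.iloc[0]
        mea, moa = str(m["effect_allele"]).upper(), str(m["other_allele"]).upper()
        ea = str(rec["effect_allele"]).upper()
        oa = str(rec["other_allele"]).upper()
        if is_ambiguous_pair(ea, oa) or is_ambiguous_pair(mea, moa):
            dropped.append((sid, "ambiguous_alleles"))
            continue
        flip = _orientation(mea, moa, ea, oa)
        if flip is None:
            dropped.append((sid, "allele_mismatch"))
            continue
        complemented = (ea, oa) not in ((mea, moa), (moa, mea))
        sign = -1.0 if flip else 1.0
        prov = ("strand_complemented+sign_flipped" if complemented and flip
                else "strand_complemented" if complemented
                else "sign_flipped" if flip else "as_is")
        rows.append({
            "snp": sid,
            "z": sign * float(rec["z"]),
            "beta": sign * float(rec["beta"]),
            "se": float(rec["se"]),
            "n": float(rec["n"]) if "n" in rec and pd.notna(rec["n"]) else np.nan,
            "provenance": prov,
            "impute_r2": np.nan,
        })
    table = pd.DataFrame(
        rows, columns=["snp", "z", "beta", "se", "n", "provenance", "impute_r2"])
    if table["z"].notna().sum() == 0:
        raise ValueError("untestable model/phenotype pair: no SNP overlap")
    return HarmonizedStats(table, dropped)


def _panel_correlation(ld_panel: GenotypeMatrix, snps: list[str]) -> np.ndarray:
    pos = ld_panel.snp_ids.get_indexer(pd.Index(snps))
    if (pos < 0).any():
        raise KeyError("LD panel does not cover requested SNPs")
    x = ld_panel.dosages[:, pos]
    xc = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, np.nan)
    r = (xc.T @ xc) / len(x) / np.outer(sd, sd)
    return np.nan_to_num(r, nan=0.0) + np.diag(np.isnan(sd) * 1.0)


def impute_missing_zscores(h: HarmonizedStats, ld_panel: GenotypeMatrix,
                           ridge_eps: float = 0.1) -> HarmonizedStats:
    """Conditional-Gaussian imputation of unobserved model-SNP z-scores.

    For the unobserved set u given observed o:
    ``z_u = S_uo (S_oo + eps I)^(-1) z_o`` with S the panel correlation
    matrix; the per-SNP imputation quality is the corresponding conditional
    r^2.  Observed entries are returned unchanged; targets absent from the
    panel stay missing (and are dropped by the association step).
    """
    t = h.table.copy()
    obs = t["z"].notna().to_numpy()
    missing = (t["provenance"] == "missing").to_numpy() & ~obs
    if not missing.any():
        return HarmonizedStats(t, list(h.dropped))
    dropped = list(h.dropped)
    in_panel = t["snp"].isin(ld_panel.snp_ids).to_numpy()
    for sid in t.loc[missing & ~in_panel, "snp"]:
        dropped.append((sid, "absent_from_panel"))
    targets = missing & in_panel
    if not targets.any() or not obs.any():
        return HarmonizedStats(t, dropped)

    obs_in_panel = obs & t["snp"].isin(ld_panel.snp_ids).to_numpy()
    snps = list(t.loc[obs_in_panel, "snp"]) + list(t.loc[targets, "snp"])
    r = _panel_correlation(ld_panel, snps)
    n_o = int(obs_in_panel.sum())
    s_oo = r[:n_o, :n_o] + ridge_eps * np.eye(n_o)
    s_uo = r[n_o:, :n_o]
    z_o = t.loc[obs_in_panel, "z"].to_numpy(dtype=float)
    solve = np.linalg.solve(s_oo, z_o)
    z_u = s_uo @ solve
    quality = np.einsum("ij,ij->i", s_uo, np.linalg.solve(s_oo, s_uo.T).T)

    idx = t.index[targets]
    t.loc[idx, "z"] = z_u
    t.loc[idx, "provenance"] = "imputed"
    t.loc[idx, "impute_r2"] = quality
    return HarmonizedStats(t, dropped)


def badgers_association(model: PredictionModel, h: HarmonizedStats,
                        ld_panel: GenotypeMatrix, ridge_eps: float = 0.1,
                        phenotype_id: str = "") -> AssociationResult:
    """Weighted-score association of an imputed metabolite with a phenotype.

    See the module docstring for the statistic.  SNPs without a usable
    harmonized z (not observed, not imputed, or absent from the panel) are
    excluded from the test along with their weights.
    """
    merged = h.table.merge(model.weights[["snp", "weight"]], on="snp")
    usable = merged["z"].notna() & (merged["weight"] != 0) \
        & merged["snp"].isin(ld_panel.snp_ids)
    merged = merged.loc[usable]
    if merged.empty:
        raise ValueError("no harmonized SNP with nonzero weight")
    snps = list(merged["snp"])
    pos = ld_panel.snp_ids.get_indexer(pd.Index(snps))
    sd = ld_panel.dosages[:, pos].std(axis=0)
    w_std = merged["weight"].to_numpy(dtype=float) * sd
    r = _panel_correlation(ld_panel, snps)
    r = (r + ridge_eps * np.eye(len(snps))) / (1.0 + ridge_eps)
    denom = float(w_std @ r @ w_std)
    if denom <= 0:
        raise ValueError("degenerate weight variance after stabilization")
    z = float(w_std @ merged["z"].to_numpy(dtype=float)) / np.sqrt(denom)
    # extreme |z| underflows the normal tail to exactly 0; keep p in (0, 1]
    p = max(float(2.0 * stats.norm.sf(abs(z))), np.finfo(float).tiny)
    return AssociationResult(
        metabolite_id=model.metabolite_id, phenotype_id=phenotype_id,
        z_score=z, p=p, n_snps_used=len(snps))


def compute_qvalues(p: np.ndarray | list, method: str = "storey",
                    fdr_cut: float = 0.05, storey_lambda: float = 0.5,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-phenotype q-values and the significant set at ``fdr_cut``.

    ``storey``: pi0 estimated at a fixed lambda (#{p > lambda} / (m (1 -
    lambda)), capped at 1) times the Benjamini-Hochberg step-up q-values;
    ``bh``: plain Benjamini-Hochberg (pi0 = 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q_bh, _, _ = multipletests(p, method="fdr_bh")
    if method == "bh":
        q = q_bh
    elif method == "storey":
        pi0 = min(1.0, float((p > storey_lambda).sum())
                  / (len(p) * (1.0 - storey_lambda)))
        pi0 = max(pi0, 1.0 / len(p))  # guard: zero pi0 breaks the estimator
        q = np.minimum(pi0 * q_bh, 1.0)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return q, q <= fdr_cut
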