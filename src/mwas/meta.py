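"""Fixed-effect inverse-variance-weighted meta-analysis of per-cohort GWAS.

Implements the standard-error-weighted fixed-effect scheme: weights are
1/se^2, the combined estimate is the weighted mean and its standard error
(sum of weights)^(-1/2), with a two-sided normal p-value.  Study effect
alleles are harmonized (sign-flipping where effect/other are swapped,
strand-complementing where needed) before combination, and only SNPs present
in every study are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import complement_allele, is_ambiguous_pair

__all__ = ["ivw_meta", "assess_replication", "ReplicationReport"]


def _orientation(rea, roa, ea, oa) -> bool | None:
    """False = as-is, True = sign flip, None = unresolvable mismatch."""
    if (ea, oa) == (rea, roa):
        return False
    if (ea, oa) == (roa, rea):
        return True
    if not is_ambiguous_pair(ea, oa):
        try:
            cea, coa = complement_allele(ea), complement_allele(oa)
        except ValueError:
            return None
        if (cea, coa) == (rea, roa):
            return False
        if (cea, coa) == (roa, rea):
            return True
    return None


def _align_to_reference(ref: pd.DataFrame, other: pd.DataFrame,
                        log: list) -> pd.DataFrame:
    """Orient ``other``'s effects to the reference study's effect alleles."""
    o = other.set_index("snp")
    o = o[o.index.isin(set(ref["snp"]))]
    ref_idx = ref.set_index("snp")
    # Fast path: alleles already identical for every shared SNP.
    r_sub = ref_idx.loc[o.index]
    same = ((r_sub["effect_allele"].to_numpy() == o["effect_allele"].to_numpy())
            & (r_sub["other_allele"].to_numpy() == o["other_allele"].to_numpy()))
    if bool(np.all(same)):
        return pd.DataFrame({
            "snp": o.index, "beta": o["beta"].to_numpy(dtype=float),
            "se": o["se"].to_numpy(dtype=float),
            "n": pd.to_numeric(o["n"], errors="coerce").to_numpy(dtype=float)
            if "n" in o else np.nan,
        })
    rows = []
    for snp, s in o.iterrows():
        r = ref_idx.loc[snp]
        flip = _orientation(str(r["effect_allele"]).upper(),
                            str(r["other_allele"]).upper(),
                            str(s["effect_allele"]).upper(),
                            str(s["other_allele"]).upper())
        if flip is None:
            log.append((snp, "allele_mismatch"))
            continue
        beta = -float(s["beta"]) if flip else float(s["beta"])
        rows.append({"snp": snp, "beta": beta, "se": float(s["se"]),
                     "n": s.get("n", np.nan)})
    return pd.DataFrame(rows, columns=["snp", "beta", "se", "n"])


def ivw_meta(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine >= 2 harmonizable GWAS result tables.

    The first study defines the reference effect alleles.  SNPs absent from
    any study, with non-positive/missing se in any study, or with
    unresolvable allele mismatches are dropped.  Output columns: snp, chr, bp,
    effect/other allele, beta, se, z, p, direction (one +/- per study),
    n_studies, n (summed where available).
    """
    if len(results) < 2:
        raise ValueError("meta-analysis needs >= 2 studies")
    log: list = []
    ref = results[0]
    aligned = [ref[["snp", "beta", "se", "n"]].copy()
               if "n" in ref else ref[["snp", "beta", "se"]].assign(n=np.nan)]
    for other in results[1:]:
        aligned.append(_align_to_reference(ref, other, log))

    snps = pd.Index(ref["snp"])
    k = len(aligned)
    betas = np.full((len(snps), k), np.nan)
    ses = np.full((len(snps), k), np.nan)
    ns = np.full((len(snps), k), np.nan)
    for i, a in enumerate(aligned):
        ai = a.set_index("snp").reindex(snps)
        betas[:, i] = ai["beta"].to_numpy(dtype=float)
        ses[:, i] = ai["se"].to_numpy(dtype=float)
        ns[:, i] = pd.to_numeric(ai["n"], errors="coerce").to_numpy(dtype=float)

    valid = (np.isfinite(betas) & np.isfinite(ses) & (ses > 0)).all(axis=1)
    bad_se = (np.isfinite(betas).all(axis=1)
              & (~np.isfinite(ses) | (ses <= 0)).any(axis=1))
    log.extend((s, "invalid_se") for s in snps[bad_se])

    b, s2 = betas[valid], ses[valid] ** 2
    w = 1.0 / s2
    beta_meta = (w * b).sum(axis=1) / w.sum(axis=1)
    se_meta = w.sum(axis=1) ** -0.5
    z = beta_meta / se_meta
    direction = ["".join("+" if x > 0 else "-" if x < 0 else "?" for x in row)
                 for row in b]
    rv = ref[valid].reset_index(drop=True)
    out = pd.DataFrame({
        "snp": rv["snp"],
        "chr": rv["chr"] if "chr" in rv else np.nan,
        "bp": rv["bp"] if "bp" in rv else np.nan,
        "effect_allele": rv["effect_allele"],
        "other_allele": rv["other_allele"],
        "beta": beta_meta, "se": se_meta, "z": z,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
        "direction": direction,
        "n_studies": k,
        "n": np.nansum(ns[valid], axis=1),
    })
    out.attrs["dropped"] = log
    return out


@dataclass
class ReplicationReport:
    """Discovery/replication bookkeeping."""

    discovery_threshold: float
    replication_threshold: float | None
    n_discovery_significant: int
    n_replicated: int
    replicated_snps: list = field(default_factory=list)
    require_sign_concordance: bool = True

    @property
    def replication_fraction(self) -> float:
        if self.n_discovery_significant == 0:
            return float("nan")
        return self.n_replicated / self.n_discovery_significant

    def to_jsonable(self) -> dict:
        return {
            "discovery_threshold": self.discovery_threshold,
            "replication_threshold": self.replication_threshold,
            "n_discovery_significant": self.n_discovery_significant,
            "n_replicated": self.n_replicated,
            "replication_fraction": self.replication_fraction,
            "replicated_snps": list(self.replicated_snps),
            "require_sign_concordance": self.require_sign_concordance,
        }


def assess_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                       disc_alpha: float = 5e-8, n_metabolites: int = 1,
                       require_sign_concordance: bool = True,
                       ) -> ReplicationReport:
    """Two-phase replication of discovery-significant SNPs.

    Discovery significance is ``disc_alpha / n_metabolites``; the replication
    threshold is 0.05 Bonferroni-corrected for the size of the discovery-
    significant set.  A SNP replicates when its replication p-value is below
    that threshold and (by default) its effect sign agrees with discovery.
    """
    disc_cut = disc_alpha / n_metabolites
    disc = discovery.dropna(subset=["p"])
    sig = disc.loc[disc["p"] < disc_cut]
    if len(sig) == 0:
        return ReplicationReport(disc_cut, None, 0, 0,
                                 require_sign_concordance=require_sign_concordance)
    rep_cut = 0.05 / len(sig)
    rep = replication.set_index("snp")
    replicated = []
    for _, r in sig.iterrows():
        snp = r["snp"]
        if snp not in rep.index:
            continue
        rr = rep.loc[snp]
        if not np.isfinite(rr["p"]) or rr["p"] >= rep_cut:
            continue
        if require_sign_concordance and np.sign(rr["beta"]) != np.sign(r["beta"]):
            continue
        replicated.append(snp)
    return ReplicationReport(disc_cut, rep_cut, len(sig), len(replicated),
                             replicated, require_sign_concordance)
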