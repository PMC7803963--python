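"""Plain-text file dialects used by the pipeline.

* genotype TSV: columns ``snp, chr, bp, a1, a2`` then one column per sample
  with dosages (a1 is the effect allele); VCF (v4.2, GT hard calls) is
  accepted as an alternative input and written as plain text.
* metabolite TSV: a ``#xenobiotic`` header line with 0/1 flags aligned to the
  metabolite columns, then a header ``sample_id, cohort, <metabolites...>``
  and one row per sample (empty cell = missing).
* covariate TSV: ``sample_id`` plus covariate columns.
* sumstats TSV: ``snp, chr, bp, effect_allele, other_allele, beta, se, p, n``
  (``or``/``z``/``eaf`` columns tolerated); METAL-dialect export uses
  MarkerName/Allele1/Allele2/Effect/StdErr/P-value/N.
* model weights TSV + JSON metadata sidecar: the exchange format between
  model training and association testing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MetaboliteMatrix, PredictionModel

__all__ = [
    "read_genotype_tsv", "write_genotype_tsv",
    "read_vcf", "write_vcf",
    "read_metabolite_tsv", "write_metabolite_tsv",
    "read_covariates_tsv", "write_covariates_tsv",
    "read_sumstats", "write_sumstats", "write_metal_sumstats",
    "write_model", "read_model", "write_truth", "read_truth",
]


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    df = g.snp_meta[["snp", "chr", "bp", "effect_allele", "other_allele"]].copy()
    df.columns = ["snp", "chr", "bp", "a1", "a2"]
    dos = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    fixed = ["snp", "chr", "bp", "a1", "a2"]
    samples = [c for c in df.columns if c not in fixed]
    dosages = df[samples].to_numpy(dtype=float).T
    f = np.nanmean(dosages, axis=0) / 2.0
    meta = pd.DataFrame({
        "snp": df["snp"].astype(str), "chr": df["chr"].astype(int),
        "bp": df["bp"].astype(int),
        "effect_allele": df["a1"].astype(str),
        "other_allele": df["a2"].astype(str),
        "maf": np.minimum(f, 1 - f),
    })
    return GenotypeMatrix(dosages, meta, pd.Index(samples))


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Plain-text VCFv4.2 with GT hard calls (dosage rounded to 0/1/2).

    REF is the other allele, ALT the effect allele, so the ALT dosage equals
    the stored effect-allele dosage.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in g.snp_meta.iterrows():
            calls = []
            for d in g.dosages[:, j]:
                calls.append("./." if np.isnan(d)
                             else gt_codes[int(round(float(d)))])
            fh.write(f"{row['chr']}\t{row['bp']}\t{row['snp']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\t"
                     "GT\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT hard calls from a VCF into effect-allele (ALT) dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,3=hom alt
        dos = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        dosage_cols.append(dos)
        rows.append({
            "snp": var.ID or f"{var.CHROM}:{var.POS}",
            "chr": int(str(var.CHROM).removeprefix("chr")),
            "bp": int(var.POS),
            "effect_allele": var.ALT[0], "other_allele": var.REF,
        })
    dosages = np.column_stack(dosage_cols) if dosage_cols else \
        np.empty((len(samples), 0))
    meta = pd.DataFrame(rows)
    f = np.nanmean(dosages, axis=0) / 2.0
    meta["maf"] = np.minimum(f, 1 - f)
    return GenotypeMatrix(dosages, meta, samples)


def write_metabolite_tsv(m: MetaboliteMatrix, path) -> None:
    with open(path, "w") as fh:
        flags = "\t".join(str(int(m.xenobiotic[c])) for c in m.values.columns)
        fh.write("#xenobiotic\t\t" + flags + "\n")
        fh.write("sample_id\tcohort\t" + "\t".join(m.values.columns) + "\n")
        for sid, row in m.values.iterrows():
            cells = ["" if pd.isna(v) else f"{v:.8g}" for v in row]
            fh.write(f"{sid}\t{m.cohort[sid]}\t" + "\t".join(cells) + "\n")


def read_metabolite_tsv(path) -> MetaboliteMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
        if first[0] != "#xenobiotic":
            raise ValueError("metabolite TSV must start with a #xenobiotic line")
        flags = [bool(int(x)) for x in first[2:]]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index.name = None
    cohort = df["cohort"].astype(str)
    values = df.drop(columns=["cohort"]).astype(float)
    xeno = pd.Series(flags, index=values.columns)
    return MetaboliteMatrix(values, xeno, cohort)


def write_covariates_tsv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def write_metal_sumstats(df: pd.DataFrame, path) -> None:
    """Export per-SNP results in the METAL column dialect."""
    out = pd.DataFrame({
        "MarkerName": df["snp"], "Allele1": df["effect_allele"],
        "Allele2": df["other_allele"], "Effect": df["beta"],
        "StdErr": df["se"], "P-value": df["p"], "N": df["n"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_model(model: PredictionModel, weights_path, meta_path) -> None:
    model.weights.to_csv(weights_path, sep="\t", index=False,
                         float_format="%.10g")
    meta = {
        "metabolite_id": model.metabolite_id,
        "family": model.family,
        "alpha": model.alpha,
        "lambda": model.lam,
        "p_threshold": model.p_threshold,
        "intercept": model.intercept,
        "cv_mean_r": None if np.isnan(model.cv_mean_r) else model.cv_mean_r,
        "cv_r2": None if np.isnan(model.cv_mean_r) else model.cv_r2,
        "n_snps_mean": None if np.isnan(model.n_snps_mean) else model.n_snps_mean,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_model(weights_path, meta_path) -> PredictionModel:
    weights = pd.read_csv(weights_path, sep="\t")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return PredictionModel(
        metabolite_id=meta["metabolite_id"], family=meta["family"],
        weights=weights, alpha=meta.get("alpha"), lam=meta.get("lambda"),
        p_threshold=meta.get("p_threshold"),
        intercept=meta.get("intercept", 0.0),
        cv_mean_r=meta["cv_mean_r"] if meta.get("cv_mean_r") is not None
        else float("nan"),
        n_snps_mean=meta["n_snps_mean"] if meta.get("n_snps_mean") is not None
        else float("nan"),
    )


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)


def read_truth(path):
    from .simulate import SimTruth

    with open(path) as fh:
        return SimTruth.from_jsonable(json.load(fh))
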