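"""End-to-end orchestration: simulate -> qc -> gwas -> meta -> train -> assoc -> mr.

A single declarative YAML config drives every stage; outputs land under an
output directory and are listed in a manifest with content hashes, so a rerun
with the same config reproduces identical hashes.  The global seed is fanned
out to per-stage sub-seeds through ``numpy.random.SeedSequence([seed, stage
index])``, keeping each stage reproducible even when other stages are
toggled off.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .gwas import (bonferroni_threshold, compute_principal_components,
                   genomic_inflation, maf_filter, run_gwas, VifExceeded)
from .meta import assess_replication, ivw_meta
from .mr import MRInput, run_all_mr
from .associate import (badgers_association, compute_qvalues,
                        harmonize_sumstats, impute_missing_zscores)
from .qc import run_qc
from .simulate import SimConfig, simulate_phenotype_sumstats, simulate_study
from .train import ClumpConfig, cross_validate_and_select, prepare_training_genotypes

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

STAGES = ("simulate", "qc", "gwas", "meta", "train", "assoc", "mr")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}] {code}: {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All pipeline parameters, with the analysis defaults.

    ``sim`` holds :class:`~mwas.simulate.SimConfig` fields; unknown keys
    anywhere are rejected so typos cannot silently fall back to defaults.
    """

    out_dir: str = "mwas_output"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)
    pcs: int = 5
    maf_cut: float = 0.05
    vif_max: float = 50.0
    genomewide_alpha: float = 5e-8
    clump_r2: float = 0.1
    clump_window_kb: float = 1000.0
    clump_p: float = 0.01
    folds: int = 4
    pgs_thresholds: list = field(default_factory=lambda: [1e-4, 1e-3, 1e-2])
    model_r2_min: float = 0.025
    fdr: float = 0.05
    fdr_method: str = "storey"
    ridge_eps: float = 0.1
    mr_n_boot: int = 1000
    # External inputs (used when the simulate stage is off).
    genotype_path: str | None = None
    metabolite_path: str | None = None
    covariate_path: str | None = None
    sumstats_paths: dict = field(default_factory=dict)  # phenotype -> path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        sim_known = set(SimConfig.__dataclass_fields__)
        sim_bad = set(cfg.sim) - sim_known
        if sim_bad:
            raise ValueError(f"unknown sim keys: {sorted(sim_bad)}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in canonical order; return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in cfg.stages]
    written: list[Path] = []
    state: dict = {}

    for stage in enabled:
        runner = globals()[f"_stage_{stage}"]
        try:
            written += runner(cfg, out, state)
        except PipelineError:
            raise
        except FileNotFoundError as exc:
            raise PipelineError(stage, "E_INPUT", str(exc)) from exc
        except Exception as exc:
            raise PipelineError(stage, "E_STAGE", str(exc)) from exc

    manifest = {
        "stages": enabled,
        "seed": cfg.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    sim = SimConfig(**{**cfg.sim, "seed": _stage_seed(cfg.seed, "simulate")})
    study = simulate_study(sim)
    sumstats = simulate_phenotype_sumstats(study.genotypes, study.truth, sim)
    state.update(study=study, sim=sim)
    paths = {
        "genotypes.tsv": lambda p: mio.write_genotype_tsv(study.genotypes, p),
        "metabolites.tsv": lambda p: mio.write_metabolite_tsv(study.metabolites, p),
        "covariates.tsv": lambda p: mio.write_covariates_tsv(study.covariates, p),
        "truth.json": lambda p: mio.write_truth(study.truth, p),
        "pheno1.sumstats.tsv": lambda p: mio.write_sumstats(sumstats, p),
    }
    written = []
    for name, writer in paths.items():
        p = out / name
        writer(p)
        written.append(p)
    state["sumstats"] = {"pheno1": sumstats}
    return written


def _require_inputs(cfg: PipelineConfig, state: dict, stage: str) -> None:
    """Load external inputs when the simulate stage was not run."""
    if "study" in state:
        return
    missing = [n for n, p in (("genotype_path", cfg.genotype_path),
                              ("metabolite_path", cfg.metabolite_path),
                              ("covariate_path", cfg.covariate_path))
               if p is None]
    if missing:
        raise PipelineError(stage, "E_INPUT",
                            f"simulate disabled and {missing} not set")
    from .simulate import SimStudy

    genotypes = (mio.read_vcf(cfg.genotype_path)
                 if str(cfg.genotype_path).endswith(".vcf")
                 else mio.read_genotype_tsv(cfg.genotype_path))
    metabolites = mio.read_metabolite_tsv(cfg.metabolite_path)
    covariates = mio.read_covariates_tsv(cfg.covariate_path)
    state["study"] = SimStudy(None, None, genotypes, metabolites,
                              covariates, None)


def _stage_qc(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _require_inputs(cfg, state, "qc")
    study = state["study"]
    cleaned, report = run_qc(study.metabolites)
    # Per-cohort missingness re-check already ran inside run_qc.
    state["cleaned"] = cleaned
    p1 = out / "metabolites.clean.tsv"
    mio.write_metabolite_tsv(cleaned, p1)
    p2 = out / "qc_report.json"
    with open(p2, "w") as fh:
        json.dump(report.to_jsonable(), fh, indent=1)
    return [p1, p2]


def _cohort_views(state: dict):
    study = state["study"]
    cleaned = state.get("cleaned", study.metabolites)
    for label in sorted(cleaned.cohort.unique()):
        ids = cleaned.cohort.index[cleaned.cohort == label]
        yield label, study.genotypes.subset_samples(ids), cleaned, ids


def _stage_gwas(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _require_inputs(cfg, state, "gwas")
    study = state["study"]
    cleaned = state.get("cleaned", study.metabolites)
    gdir = out / "gwas"
    gdir.mkdir(exist_ok=True)
    written = []
    results: dict = {}
    lambdas: dict = {}
    for label, g_cohort, mm, ids in _cohort_views(state):
        pcs, _ = compute_principal_components(g_cohort, cfg.pcs)
        cov = study.covariates.loc[ids].join(pcs)
        if cov["batch"].nunique() <= 1:  # batch is constant within cohort
            cov = cov.drop(columns=["batch"])
        for met in cleaned.values.columns:
            y = mm.values.loc[ids, met]
            try:
                res = run_gwas(g_cohort, y, cov, vif_max=cfg.vif_max)
            except VifExceeded:
                results.setdefault(met, {})[label] = None
                continue
            res = maf_filter(res, cfg.maf_cut)
            results.setdefault(met, {})[label] = res
            lambdas[f"{met}:{label}"] = genomic_inflation(res["p"])
            p = gdir / f"{met}.{label}.tsv"
            mio.write_metal_sumstats(res, p)
            written.append(p)
    state["gwas"] = results
    p = out / "genomic_inflation.json"
    pooled = [v for v in lambdas.values() if np.isfinite(v)]
    with open(p, "w") as fh:
        json.dump({"per_gwas": lambdas,
                   "median": float(np.median(pooled)) if pooled else None},
                  fh, indent=1, sort_keys=True)
    written.append(p)
    return written


def _stage_meta(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    if "gwas" not in state:
        raise PipelineError("meta", "E_INPUT", "gwas stage results unavailable")
    mdir = out / "meta"
    mdir.mkdir(exist_ok=True)
    written = []
    metas: dict = {}
    n_metabolites = len(state["gwas"])
    rep_summary = {}
    for met, per_cohort in state["gwas"].items():
        tables = [t for t in per_cohort.values() if t is not None]
        if len(tables) < 2:
            continue
        meta = ivw_meta(tables)
        metas[met] = meta
        p = mdir / f"{met}.meta.tsv"
        mio.write_sumstats(meta.rename(columns={"z": "stat"}), p)
        written.append(p)
        rep = assess_replication(tables[0], tables[1],
                                 disc_alpha=cfg.genomewide_alpha,
                                 n_metabolites=max(n_metabolites, 1))
        rep_summary[met] = rep.to_jsonable()
    state["meta"] = metas
    p = out / "replication.json"
    with open(p, "w") as fh:
        json.dump(rep_summary, fh, indent=1, sort_keys=True)
    written.append(p)
    return written


def _stage_train(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _require_inputs(cfg, state, "train")
    study = state["study"]
    cleaned = state.get("cleaned", study.metabolites)
    g = prepare_training_genotypes(study.genotypes, maf_min=cfg.maf_cut)
    g = g.subset_samples(cleaned.cohort.index)
    pcs, _ = compute_principal_components(g, cfg.pcs)
    cov = study.covariates.loc[g.sample_ids].join(pcs)
    clump = ClumpConfig(cfg.clump_r2, cfg.clump_window_kb, cfg.clump_p)
    seed = _stage_seed(cfg.seed, "train")
    tdir = out / "models"
    tdir.mkdir(exist_ok=True)
    written = []
    models: dict = {}
    summary = []
    for met in cleaned.values.columns:
        sel = cross_validate_and_select(
            cleaned.values[met], g, cov, cleaned.cohort,
            folds=cfg.folds, seed=seed,
            pgs_thresholds=tuple(cfg.pgs_thresholds),
            clump_cfg=clump, vif_max=cfg.vif_max, metabolite_id=met)
        row = {"metabolite": met, "excluded": sel.excluded_reason or ""}
        if sel.best_model is not None:
            m = sel.best_model
            row.update(family=m.family, alpha=m.alpha, l1_lambda=m.lam,
                       p_threshold=m.p_threshold, cv_mean_r=m.cv_mean_r,
                       cv_r2=m.cv_r2, n_snps=m.n_snps,
                       included=m.passes_inclusion_filter(cfg.model_r2_min))
            if m.passes_inclusion_filter(cfg.model_r2_min):
                models[met] = m
                wp = tdir / f"{met}.weights.tsv"
                mp = tdir / f"{met}.meta.json"
                mio.write_model(m, wp, mp)
                written += [wp, mp]
        summary.append(row)
    state["models"] = models
    p = out / "model_summary.tsv"
    pd.DataFrame(summary).to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)
    return written


def _load_phenotype_sumstats(cfg: PipelineConfig, state: dict, stage: str) -> dict:
    if "sumstats" in state:
        return state["sumstats"]
    if not cfg.sumstats_paths:
        raise PipelineError(stage, "E_INPUT",
                            "no phenotype summary statistics available")
    loaded = {}
    for pheno, path in cfg.sumstats_paths.items():
        if not Path(path).exists():
            raise PipelineError(stage, "E_INPUT", f"missing sumstats: {path}")
        loaded[pheno] = mio.read_sumstats(path)
    state["sumstats"] = loaded
    return loaded


def _stage_assoc(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    if "models" not in state:
        raise PipelineError("assoc", "E_INPUT", "trained models unavailable")
    sumstats = _load_phenotype_sumstats(cfg, state, "assoc")
    study = state["study"]
    panel = study.genotypes
    rows = []
    for pheno, st in sumstats.items():
        for met, model in state["models"].items():
            try:
                h = harmonize_sumstats(model, st)
                h = impute_missing_zscores(h, panel, ridge_eps=cfg.ridge_eps)
                res = badgers_association(model, h, panel,
                                          ridge_eps=cfg.ridge_eps,
                                          phenotype_id=pheno)
            except (ValueError, KeyError):
                continue
            rows.append({"metabolite": met, "phenotype": pheno,
                         "z": res.z_score, "p": res.p,
                         "n_snps": res.n_snps_used})
    assoc = pd.DataFrame(rows)
    if len(assoc):
        qs = np.full(len(assoc), np.nan)
        sig = np.zeros(len(assoc), dtype=bool)
        for pheno in assoc["phenotype"].unique():
            m = (assoc["phenotype"] == pheno).to_numpy()
            q, s = compute_qvalues(assoc.loc[m, "p"].to_numpy(),
                                   method=cfg.fdr_method, fdr_cut=cfg.fdr)
            qs[m], sig[m] = q, s
        assoc["q"], assoc["significant_fdr"] = qs, sig
        n_tests = assoc.shape[0]
        assoc["significant_bonferroni"] = \
            assoc["p"] < bonferroni_threshold(0.05, n_tests)
    state["assoc"] = assoc
    p = out / "associations.tsv"
    assoc.to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]


def _stage_mr(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    if "assoc" not in state or "models" not in state or "meta" not in state:
        raise PipelineError("mr", "E_INPUT",
                            "assoc/meta stage results unavailable")
    sumstats = state["sumstats"]
    seed = _stage_seed(cfg.seed, "mr")
    rows = []
    assoc = state["assoc"]
    sig = assoc.loc[assoc["significant_fdr"]] if len(assoc) else assoc
    for _, a in sig.iterrows():
        met, pheno = a["metabolite"], a["phenotype"]
        model = state["models"].get(met)
        meta = state["meta"].get(met)
        if model is None or meta is None:
            continue
        inst = model.weights.loc[model.weights["weight"] != 0, "snp"]
        exp = meta.set_index("snp")
        outc = sumstats[pheno].set_index("snp")
        keep = [s for s in inst if s in exp.index and s in outc.index]
        if not keep:
            continue
        # Both tables are oriented to the panel effect alleles upstream.
        mri = MRInput(
            beta_exposure=exp.loc[keep, "beta"].to_numpy(dtype=float),
            se_exposure=exp.loc[keep, "se"].to_numpy(dtype=float),
            beta_outcome=outc.loc[keep, "beta"].to_numpy(dtype=float),
            se_outcome=outc.loc[keep, "se"].to_numpy(dtype=float),
            snp_ids=keep)
        res = run_all_mr(mri, n_boot=cfg.mr_n_boot, seed=seed)
        res.insert(0, "phenotype", pheno)
        res.insert(0, "metabolite", met)
        rows.append(res)
    mr_out = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["metabolite", "phenotype", "method",
                                         "estimate", "se", "p",
                                         "n_instruments", "egger_intercept",
                                         "egger_intercept_p"]))
    if len(mr_out):
        mr_out["significant"] = \
            mr_out["p"] < bonferroni_threshold(0.05, len(mr_out))
    p = out / "mr_results.tsv"
    mr_out.to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]
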