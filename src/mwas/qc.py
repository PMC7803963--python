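"""Metabolite matrix cleaning.

The filter chain, in order: class-specific missingness filters (non-xenobiotics
removed at >= 30% missing, xenobiotics at >= 80%), sample filter (>= 40% of
metabolites missing), zero-IQR filter, half-minimum imputation within cohort
for non-xenobiotics only, log10 transform, and — after any external sample
subsetting — a per-cohort >= 50% missingness re-check.  All thresholds are
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MetaboliteMatrix

__all__ = [
    "QCReport",
    "apply_missingness_filters",
    "filter_zero_iqr",
    "impute_half_minimum",
    "log10_transform",
    "recheck_per_cohort_missingness",
    "run_qc",
]

REASON_CODES = ("nonxeno_miss", "xeno_miss", "zero_iqr", "post_clean_miss")


@dataclass
class QCReport:
    """What was removed or imputed, and why."""

    removed_metabolites: list = field(default_factory=list)  # (id, reason)
    removed_samples: list = field(default_factory=list)
    imputed_cells: dict = field(default_factory=dict)  # cohort -> count
    empty_after_filtering: bool = False

    def merge(self, other: "QCReport") -> "QCReport":
        merged = QCReport(
            removed_metabolites=self.removed_metabolites + other.removed_metabolites,
            removed_samples=self.removed_samples + other.removed_samples,
            imputed_cells={**self.imputed_cells},
            empty_after_filtering=self.empty_after_filtering
            or other.empty_after_filtering,
        )
        for k, v in other.imputed_cells.items():
            merged.imputed_cells[k] = merged.imputed_cells.get(k, 0) + v
        return merged

    def to_jsonable(self) -> dict:
        return {
            "removed_metabolites": [list(t) for t in self.removed_metabolites],
            "removed_samples": list(self.removed_samples),
            "imputed_cells": dict(self.imputed_cells),
            "empty_after_filtering": self.empty_after_filtering,
        }


def _check_cut(name: str, value: float) -> None:
    if not 0.0 < value <= 1.0:
        raise ValueError(f"{name} must be in (0, 1], got {value}")


def apply_missingness_filters(m: MetaboliteMatrix,
                              nonxeno_cut: float = 0.30,
                              xeno_cut: float = 0.80,
                              sample_cut: float = 0.40,
                              ) -> tuple[MetaboliteMatrix, QCReport]:
    """Class-specific metabolite missingness filters, then the sample filter.

    A non-xenobiotic is removed when missing for >= ``nonxeno_cut`` of samples,
    a xenobiotic at >= ``xeno_cut``; afterwards any sample missing >=
    ``sample_cut`` of the remaining metabolites is removed.  Boundaries are
    inclusive.
    """
    for nm, v in (("nonxeno_cut", nonxeno_cut), ("xeno_cut", xeno_cut),
                  ("sample_cut", sample_cut)):
        _check_cut(nm, v)
    report = QCReport()
    miss_frac = m.values.isna().mean(axis=0)
    cut = np.where(m.xenobiotic.to_numpy(), xeno_cut, nonxeno_cut)
    drop = miss_frac.to_numpy() >= cut - 1e-12
    for name, is_x in zip(m.values.columns[drop], m.xenobiotic.to_numpy()[drop]):
        report.removed_metabolites.append(
            (name, "xeno_miss" if is_x else "nonxeno_miss"))
    values = m.values.loc[:, ~drop]

    if values.shape[1] > 0:
        sample_miss = values.isna().mean(axis=1)
        bad = sample_miss.to_numpy() >= sample_cut - 1e-12
    else:
        bad = np.zeros(values.shape[0], dtype=bool)
    report.removed_samples.extend(values.index[bad])
    values = values.loc[~bad]

    if values.size == 0:
        report.empty_after_filtering = True
    out = MetaboliteMatrix(values, m.xenobiotic.loc[values.columns],
                           m.cohort.loc[values.index])
    return out, report


def filter_zero_iqr(m: MetaboliteMatrix) -> tuple[MetaboliteMatrix, QCReport]:
    """Drop metabolites whose observed values have an interquartile range of 0.

    Quartiles use linear interpolation between order statistics; metabolites
    with fewer than two observed values carry no variation and are removed.
    """
    report = QCReport()
    keep = []
    for name in m.values.columns:
        obs = m.values[name].dropna().to_numpy()
        if len(obs) < 2:
            report.removed_metabolites.append((name, "zero_iqr"))
            continue
        q1, q3 = np.quantile(obs, [0.25, 0.75])  # linear interpolation
        if q3 - q1 == 0.0:
            report.removed_metabolites.append((name, "zero_iqr"))
        else:
            keep.append(name)
    values = m.values.loc[:, keep]
    if values.size == 0:
        report.empty_after_filtering = True
    return (MetaboliteMatrix(values, m.xenobiotic.loc[keep], m.cohort.copy()),
            report)


def impute_half_minimum(m: MetaboliteMatrix) -> tuple[MetaboliteMatrix, QCReport]:
    """Below-detection imputation: half the within-cohort minimum.

    Missing non-xenobiotic cells are set to 0.5 x the minimum observed value of
    that metabolite within the sample's cohort (the missingness is assumed to
    reflect a level below the detection limit).  Xenobiotic cells stay missing:
    a xenobiotic can genuinely be absent.
    """
    report = QCReport()
    values = m.values.copy()
    for cohort_label, sample_idx in m.cohort.groupby(m.cohort).groups.items():
        block = values.loc[sample_idx]
        count = 0
        for name in values.columns:
            if m.xenobiotic[name]:
                continue
            col = block[name]
            n_missing = int(col.isna().sum())
            if n_missing == 0:
                continue
            observed = col.dropna()
            if observed.empty:
                raise ValueError(
                    f"metabolite {name!r} has no observed values in cohort "
                    f"{cohort_label!r}; half-minimum imputation undefined")
            fill = 0.5 * observed.min()
            values.loc[sample_idx, name] = col.fillna(fill)
            count += n_missing
        if count:
            report.imputed_cells[str(cohort_label)] = count
    return MetaboliteMatrix(values, m.xenobiotic.copy(), m.cohort.copy()), report


def log10_transform(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Elementwise log10 of observed abundances (right-skew correction)."""
    bad = (m.values <= 0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(
            f"non-positive abundance for metabolite {col!r}, sample {row!r}: "
            "log10 transform undefined")
    return MetaboliteMatrix(np.log10(m.values), m.xenobiotic.copy(),
                            m.cohort.copy())


def recheck_per_cohort_missingness(m: MetaboliteMatrix,
                                   post_clean_cut: float = 0.50,
                                   ) -> tuple[MetaboliteMatrix, QCReport]:
    """Post-cleaning re-check: drop metabolites missing >= cut in any cohort.

    Run after external sample subsetting (e.g. restriction to genotyped
    samples) so every metabolite retains enough observations per cohort for
    stable per-cohort GWAS.
    """
    _check_cut("post_clean_cut", post_clean_cut)
    report = QCReport()
    drop = set()
    for _, sample_idx in m.cohort.groupby(m.cohort).groups.items():
        frac = m.values.loc[sample_idx].isna().mean(axis=0)
        for name in frac.index[frac.to_numpy() >= post_clean_cut - 1e-12]:
            drop.add(name)
    for name in m.values.columns:
        if name in drop:
            report.removed_metabolites.append((name, "post_clean_miss"))
    keep = [c for c in m.values.columns if c not in drop]
    values = m.values.loc[:, keep]
    if values.size == 0:
        report.empty_after_filtering = True
    return (MetaboliteMatrix(values, m.xenobiotic.loc[keep], m.cohort.copy()),
            report)


def run_qc(m: MetaboliteMatrix,
           nonxeno_cut: float = 0.30, xeno_cut: float = 0.80,
           sample_cut: float = 0.40, post_clean_cut: float = 0.50,
           ) -> tuple[MetaboliteMatrix, QCReport]:
    """The full cleaning chain in the canonical order."""
    out, rep = apply_missingness_filters(m, nonxeno_cut, xeno_cut, sample_cut)
    out, r2 = filter_zero_iqr(out)
    rep = rep.merge(r2)
    if out.values.size == 0:
        return out, rep
    out, r3 = impute_half_minimum(out)
    rep = rep.merge(r3)
    out = log10_transform(out)
    out, r4 = recheck_per_cohort_missingness(out, post_clean_cut)
    return out, rep.merge(r4)
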