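"""Convenience QQ and Manhattan plots for per-SNP results."""

from __future__ import annotations

import numpy as np
import pandas as pd


def qq_plot(p, ax=None):
    """Observed vs expected -log10 p-values with the identity line."""
    import matplotlib.pyplot as plt

    p = np.sort(pd.Series(p).dropna().to_numpy())
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(p)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(exp, obs, s=4)
    lim = max(exp.max(), obs.max()) if n else 1.0
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    return ax


def manhattan_plot(result: pd.DataFrame, threshold: float | None = None,
                   ax=None):
    """Per-SNP -log10 p by genomic position, colored by chromosome."""
    import matplotlib.pyplot as plt

    df = result.dropna(subset=["p"]).sort_values(["chr", "bp"])
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(df.groupby("chr", sort=True)):
        x = offset + grp["bp"].to_numpy() / 1e6
        ax.scatter(x, -np.log10(grp["p"]), s=4,
                   color="C0" if i % 2 == 0 else "C1")
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + 5
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=1, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("$-\\log_{10} p$")
    return ax
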