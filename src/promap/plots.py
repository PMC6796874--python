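"""Diagnostic plots: MA plot with significance coloring, rescaled QQ summary."""

from __future__ import annotations

import numpy as np


def ma_plot(result, ax=None, alpha_level: float = 0.05):
    """MA scatter colored by -log10 adjusted P, with the +/-2 sigma band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    table = result.table
    sc = ax.scatter(
        table["A"],
        table["M"],
        c=-np.log10(table["P_adj"]),
        s=4,
        cmap="viridis",
        rasterized=True,
    )
    order = np.argsort(table["A"].to_numpy())
    band = 2.0 * np.sqrt(table["sigma2"].to_numpy()[order])
    ax.plot(table["A"].to_numpy()[order], band, "r--", lw=1)
    ax.plot(table["A"].to_numpy()[order], -band, "r--", lw=1)
    ax.set_xlabel("A (mean log2 intensity)")
    ax.set_ylabel("M (log2 ratio)")
    plt.colorbar(sc, ax=ax, label="-log10 adjusted P")
    return ax


def rescaled_qq_plot(summary, ax=None):
    """Mean +/- SD of window-rescaled ordered ratios against normal quantiles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(
        summary["q"],
        summary["mean"],
        yerr=summary["sd"],
        fmt=".",
        ms=3,
        ecolor="lightgray",
        elinewidth=0.5,
    )
    lim = float(np.nanmax(np.abs(summary["q"]))) * 1.05
    ax.plot([-lim, lim], [-lim, lim], "r-", lw=1, label="y = x")
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("rescaled ordered log2 ratio")
    ax.legend()
    return ax
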