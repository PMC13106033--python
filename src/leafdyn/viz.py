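"""Minimal plotting helpers for the model results objects."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_quadratic_trend", "plot_candidate_scatter"]


def plot_quadratic_trend(trend, ages, values=None, ax=None, label=None):
    """Fitted parabola with its pointwise confidence band.

    ``trend`` is a :class:`leafdyn.ageing.QuadraticTrend`; ``ages`` the
    evaluation grid; ``values`` optional observed points to scatter.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(np.min(ages), np.max(ages), 200)
    fit = trend.predict(grid)
    half = trend.ci_halfwidth(grid)
    ax.plot(grid, fit, label=label)
    ax.fill_between(grid, fit - half, fit + half, alpha=0.25)
    if values is not None:
        ax.scatter(ages, values, s=12, alpha=0.6)
    ax.set_xlabel("leaf age (days)")
    ax.set_ylabel("expression")
    return ax


def plot_candidate_scatter(ranked, ax=None, top_n=5):
    """Two-measure candidate view: shoot-size correlation vs drought axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    elig = ranked[ranked["eligible"]]
    rest = ranked[~ranked["eligible"]]
    ax.scatter(rest["r_shoot"], rest["drought_neglog10_padj"], s=8, c="lightgray")
    ax.scatter(elig["r_shoot"], elig["drought_neglog10_padj"], s=12, c="tab:red")
    for _, row in elig.head(top_n).iterrows():
        ax.annotate(row["gene_id"], (row["r_shoot"], row["drought_neglog10_padj"]), fontsize=7)
    ax.set_xlabel("Pearson r (expression vs shoot area)")
    ax.set_ylabel("-log10 adjusted p (drought response)")
    return ax
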