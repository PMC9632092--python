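"""Diagnostic plots: the four-panel per-gene report.

Panel layout: (a) histogram with the fitted mixture density and cutoff
lines — bins entirely below the background intersection shaded pink,
bins below the two-sigma background bound shaded yellow; (b) BIC of the
1- and 2-component fits along the trimming trajectory; (c) bar chart of
the categorized group fractions; (d) chi-square of both fits along the
trajectory, with the selected optimum marked.
"""

from __future__ import annotations

import numpy as np

from .binning import dynamic_histogram
from .tailtrim import GeneCategorization

__all__ = ["four_panel_figure"]


def four_panel_figure(
    values,
    cat: GeneCategorization,
    background_intersection: float | None = None,
    background_two_sigma: float | None = None,
    title: str = "",
):
    """Build the 4-panel diagnostic figure for one gene.

    Returns a matplotlib Figure; callers save or show it.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax_hist, ax_bic, ax_bar, ax_chi = axes.ravel()

    # (a) histogram + fitted density
    try:
        hist = dynamic_histogram(x)
        widths = np.diff(hist.edges)
        for lo, w, c in zip(hist.edges[:-1], widths, hist.counts):
            color = "0.7"
            if background_two_sigma is not None and lo + w <= background_two_sigma:
                color = "gold"
            if background_intersection is not None and lo + w <= background_intersection:
                color = "pink"
            ax_hist.bar(lo, c, width=w, align="edge", color=color,
                        edgecolor="black", linewidth=0.5)
        if cat.fit is not None:
            grid = np.linspace(x.min(), x.max(), 400)
            dens = cat.fit.pdf(grid)
            # scale density to count space via mean bin width
            ax_hist.plot(grid, dens * hist.n * widths.mean(), color="navy")
        for cut in cat.cutoffs:
            ax_hist.axvline(cut, color="red", linestyle="--")
    except Exception:  # degenerate inputs still get the other panels
        pass
    ax_hist.set_xlabel("log2 expression")
    ax_hist.set_ylabel("samples")
    ax_hist.set_title(f"{title} ({cat.pattern})".strip())

    # (b)/(d) trajectories
    if cat.trajectory is not None and len(cat.trajectory):
        traj = cat.trajectory
        for side, grp in traj.groupby("side"):
            sgn = {"none": "", "low": "-low", "high": "-high"}[side]
            ax_bic.plot(grp["n_removed"], grp["bic_1"], "b.-",
                        label=f"1 comp{sgn}" if side != "high" else None)
            ax_bic.plot(grp["n_removed"], grp["bic_2"], "r.-",
                        label=f"2 comp{sgn}" if side != "high" else None)
            ax_chi.plot(grp["n_removed"], grp["chi2_1"], "b.-")
            ax_chi.plot(grp["n_removed"], grp["chi2_2"], "r.-")
        ax_chi.axhline(2**cat.threshold_log2_chi2, color="0.5",
                       linestyle=":", label="tail threshold")
        if cat.gof is not None:
            ax_chi.plot([cat.n_tail], [cat.chi2], "k*", markersize=12,
                        label="selected")
        ax_bic.legend(fontsize=8)
        ax_chi.legend(fontsize=8)
    ax_bic.set_xlabel("points removed")
    ax_bic.set_ylabel("BIC")
    ax_chi.set_xlabel("points removed")
    ax_chi.set_ylabel("chi-square")

    # (c) category bar chart
    labs, counts = np.unique(cat.labels, return_counts=True)
    ax_bar.bar([str(int(l)) for l in labs], 100.0 * counts / counts.sum(),
               color="steelblue")
    ax_bar.set_xlabel("category")
    ax_bar.set_ylabel("% of samples")

    fig.tight_layout()
    return fig
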