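"""Optional, cosmetic plot rendering for the analysis tables.

The tab-separated tables are the canonical outputs; these helpers only
render them.  matplotlib is imported lazily so the core pipeline has no
plotting dependency at import time.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_slp(slp_matrix, path) -> None:
    """Strand-linkage heatmap with marginal histograms."""
    plt = _plt()
    fig, axes = plt.subplots(
        2, 2, figsize=(7, 7),
        gridspec_kw={"height_ratios": [1, 4], "width_ratios": [4, 1]},
    )
    mat = slp_matrix.matrix
    axes[1, 0].imshow(
        mat.to_numpy(), aspect="auto", origin="lower", cmap="viridis",
        extent=[mat.columns[0], mat.columns[-1], mat.index[0], mat.index[-1]],
    )
    axes[1, 0].set_xlabel("bottom-strand nick (bond)")
    axes[1, 0].set_ylabel("top-strand nick (bond)")
    axes[0, 0].bar(mat.columns, slp_matrix.bottom_marginal, color="black")
    axes[1, 1].barh(mat.index, slp_matrix.top_marginal, color="black")
    axes[0, 1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(tornado_df, path, pmf=None, origin: int = 0) -> None:
    """Events ranked by spacing, midpoints crossed, optional collision law."""
    plt = _plt()
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(7, 7), sharex=True, gridspec_kw={"height_ratios": [3, 1]}
    )
    colors = {"3p": "tab:orange", "5p": "tab:blue", "blunt": "grey"}
    for _, row in tornado_df.iterrows():
        half = row.abs_spacing / 2.0
        ax.hlines(
            row["rank"], row.midpoint - half, row.midpoint + half,
            color=colors.get(row.overhang_class, "grey"), lw=0.8,
        )
        ax.plot(row.midpoint, row["rank"], "k+", ms=3)
    ax.invert_yaxis()
    ax.set_ylabel("event rank (by |spacing|)")
    mids = tornado_df["midpoint"].to_numpy()
    if len(mids):
        lo, hi = mids.min() - 20, mids.max() + 20
        bins = np.arange(lo, hi + 1)
        axh.hist(mids, bins=bins, color="grey")
        if pmf is not None:
            x = origin + np.arange(len(pmf))
            axh.plot(x, pmf * len(mids), "k-", lw=1)
    axh.set_xlabel("reference position (bond)")
    axh.set_ylabel("midpoints / bp")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
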