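"""Plotting helpers (regional association panels)."""

from __future__ import annotations

import numpy as np

from .sumstats import SummaryDataset


def plot_regional(trait1: SummaryDataset, trait2: SummaryDataset, path) -> None:
    """Two-panel regional -log10(p) plot for a colocalization pair."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    for ax, ds in zip(axes, (trait1, trait2)):
        pos = np.array([r.variant.pos for r in ds]) / 1e6
        logp = -np.log10([r.pvalue for r in ds])
        ax.scatter(pos, logp, s=8, c="#355C7D")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.set_title(ds.trait_id, fontsize=9, loc="left")
    axes[1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
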