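"""Figure helpers: snapshot histograms and sweep heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import transform_display

__all__ = ["plot_snapshot_histograms", "plot_mechanism_heatmap"]


def plot_snapshot_histograms(snapshots: dict, observable: str, path,
                             shift: float = 0.01, bins: int = 60):
    """Overlaid per-condition histograms on a log10-shift display axis.

    ``snapshots`` maps condition label -> per-cell snapshot DataFrame.
    """
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, df in snapshots.items():
        disp = transform_display(df[observable].to_numpy(),
                                 mode="log10_shift", c=shift)
        ax.hist(disp, bins=bins, histtype="step", density=True, label=label)
    ax.set_xlabel(f"log10({observable} + {shift:g})")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_mechanism_heatmap(sweep: pd.DataFrame, readout: str, path):
    """Mechanism x multiplier heatmap of a 12 hps readout, log2 fold vs 1x."""
    grid = np.sort(sweep.multiplier.unique())
    mechs = np.sort(sweep.mechanism.unique())
    mat = np.zeros((len(mechs), len(grid)))
    for i, mech in enumerate(mechs):
        g = sweep[sweep.mechanism == mech].sort_values("multiplier")
        base = g.loc[np.isclose(g.multiplier, 1.0), readout].iloc[0]
        mat[i] = np.log2(np.maximum(g[readout].to_numpy(), 1e-12) / base)
    fig, ax = plt.subplots(figsize=(4.5, 3))
    vmax = max(np.abs(mat).max(), 1e-6)
    im = ax.imshow(mat, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(grid)), [f"{m:g}x" for m in grid], fontsize=7)
    ax.set_yticks(range(len(mechs)), [f"#{m}" for m in mechs], fontsize=7)
    ax.set_xlabel("effect magnitude")
    ax.set_ylabel("mechanism")
    fig.colorbar(im, label=f"log2 fold {readout}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
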