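"""Minimal plotting helpers for the enrichment and co-occurrence matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd


def save_heatmap(frame: pd.DataFrame, path, title: str = "",
                 cmap: str = "RdBu_r") -> None:
    """Save a signed-score matrix (e.g. signed log10 p) as a heat map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = frame.to_numpy(dtype=float)
    lim = max(1.0, np.nanmax(np.abs(values)))
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * frame.shape[1], 1 + 0.4 * frame.shape[0]))
    im = ax.imshow(values, cmap=cmap, vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(frame.shape[0]), frame.index)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="signed log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
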