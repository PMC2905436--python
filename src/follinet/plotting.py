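"""Static plot helpers: TOM heatmap and module dendrogram."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_tom_heatmap", "plot_dendrogram"]


def plot_tom_heatmap(tom: pd.DataFrame, order: np.ndarray | None = None, ax=None):
    """Heatmap of the topological overlap matrix, optionally leaf-ordered."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    m = tom.to_numpy()
    if order is not None:
        m = m[np.ix_(order, order)]
    ax.imshow(1.0 - m, cmap="YlOrRd_r", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("Topological overlap")
    return ax


def plot_dendrogram(Z: np.ndarray, labels=None, ax=None):
    """Average-linkage dendrogram of the 1-TOM clustering."""
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    dendrogram(Z, ax=ax, no_labels=labels is None, labels=labels,
               color_threshold=0.0, link_color_func=lambda _: "k")
    ax.set_ylabel("1 - TOM")
    return ax
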