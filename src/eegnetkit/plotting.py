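"""Figure-style exports: connectivity heatmaps and summary plots."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


def export_heatmap(
    cm: ConnectivityMatrix,
    path: str | Path,
    scale: tuple[float, float] = (0.0, 0.6),
) -> dict:
    """Write a channel x channel heatmap with a fixed 0-0.6 color scale.

    Values above the scale top are clipped by the colormap; the clip count is
    logged and returned so saturated matrices are visible in the run log.
    """
    path = Path(path)
    vmin, vmax = scale
    off_diag = cm.weights[~np.eye(cm.n_nodes, dtype=bool)]
    n_clipped = int((off_diag > vmax).sum())
    if n_clipped:
        logger.info("%d connectivity value(s) above %.2f clipped in %s", n_clipped, vmax, path.name)

    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    im = ax.imshow(cm.weights, vmin=vmin, vmax=vmax, cmap="jet", interpolation="nearest")
    ticks = range(cm.n_nodes)
    ax.set_xticks(ticks, cm.channel_labels, rotation=90, fontsize=6)
    ax.set_yticks(ticks, cm.channel_labels, fontsize=6)
    ax.set_title(f"{cm.band} {cm.order}-order connectivity", fontsize=9)
    fig.colorbar(im, ax=ax, label="connectivity strength")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return {"path": str(path), "n_clipped": n_clipped, "scale": [vmin, vmax]}
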