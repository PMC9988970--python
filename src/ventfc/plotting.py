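"""Schematic rendering of group t-maps over the cap montage."""

from __future__ import annotations

import numpy as np

from .connectivity import GroupTMap


def channel_positions(montage) -> np.ndarray:
    """Midpoint of each channel's source/detector pair (mm)."""
    src = {o.id: np.asarray(o.pos_mm) for o in montage.sources}
    det = {o.id: np.asarray(o.pos_mm) for o in montage.detectors}
    return np.array([(src[c.source] + det[c.detector]) / 2.0 for c in montage.channels])


def plot_tmap(tmap: GroupTMap, path: str, alpha: float = 0.05) -> None:
    """Draw channel-pair t-values as colored arcs over the optode layout."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    montage = tmap.montage
    pos = channel_positions(montage)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(*montage.source_positions().T, marker="s", c="crimson", label="sources")
    ax.scatter(*montage.detector_positions().T, marker="o", c="navy", label="detectors")
    finite = tmap.t[np.isfinite(tmap.t)]
    tmax = max(np.abs(finite).max(), 1e-9) if finite.size else 1.0
    cmap = plt.get_cmap("coolwarm")
    n = montage.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            t = tmap.t[i, j]
            if not np.isfinite(t):
                continue
            sig = tmap.p[i, j] < alpha
            ax.plot(*zip(pos[i], pos[j]), color=cmap(0.5 + 0.5 * t / tmax),
                    lw=2.0 if sig else 0.6, alpha=0.9 if sig else 0.35)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"group sFC t-map ({tmap.chromophore}); bold: p < {alpha}")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
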