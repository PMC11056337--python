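"""Inspection plots (optional; requires matplotlib).

Plain orthogonal-slice rendering of volumes/Z maps and a simple ROC plot.
These are conveniences for eyeballing phantom runs, not part of the
analysis contract.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import ROCResult
from .volume import ImageVolume


def save_orthogonal_slices(vol: ImageVolume, path: str | Path, title: str = "") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(vol.values, dtype=float)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.4))
    mids = [s // 2 for s in vol.grid.shape]
    slices = [vals[mids[0], :, :], vals[:, mids[1], :], vals[:, :, mids[2]]]
    names = ["sagittal", "coronal", "axial"]
    for ax, sl, name in zip(axes, slices, names):
        im = ax.imshow(sl.T, origin="lower", cmap="viridis")
        ax.set_title(name, fontsize=9)
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.046)
    if title:
        fig.suptitle(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def save_roc_plot(results: dict[str, ROCResult], path: str | Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    for label, roc in results.items():
        ax.plot(1.0 - roc.specificity, roc.sensitivity,
                label=f"{label} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path
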