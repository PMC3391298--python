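"""Static plots: the 3D ROC surface and the FDR-colored ROC curve.

The surface is ruled: at each TPR level it spans FPR from the curve
point to 1 at height TDR, and its floor projection onto the FPR-TPR
plane is the area under the ordinary ROC curve. Output is a static
image file (PNG/SVG/PDF by extension).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from mpl_toolkits.mplot3d.art3d import Poly3DCollection

from .curves import RocsCurve
from . import metrics

__all__ = ["plot_rocs", "plot_roc_fdr"]


def _step_outline(curve: RocsCurve, height: np.ndarray | None = None):
    """Vertices of the step curve from the (0, 0) origin, optionally with
    a per-point height sequence carried along."""
    fpr = np.r_[0.0, curve.fpr]
    tpr = np.r_[0.0, curve.tpr]
    h = None if height is None else np.r_[height[0], height]
    # step: horizontal move in FPR at the previous TPR, then vertical rise
    xs, ys, zs = [fpr[0]], [tpr[0]], [] if h is None else [h[0]]
    for k in range(1, fpr.size):
        xs += [fpr[k], fpr[k]]
        ys += [tpr[k - 1], tpr[k]]
        if h is not None:
            zs += [h[k], h[k]]
    if h is None:
        return np.array(xs), np.array(ys)
    return np.array(xs), np.array(ys), np.array(zs)


def plot_rocs(curve: RocsCurve, output_path: str | Path) -> Path:
    """Render the 3D ROC surface and its floor projection to a file.

    The colored sheet spans, at each TPR level, FPR from the operating
    point to 1 at height TDR; the grey floor polygon is the area under
    the ordinary ROC curve.
    """
    output_path = Path(output_path)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")

    xs, ys, zs = _step_outline(curve, curve.tdr)
    # ruled surface between the lifted step curve and the FPR = 1 edge
    X = np.vstack([xs, np.ones_like(xs)])
    Y = np.vstack([ys, ys])
    Z = np.vstack([zs, zs])
    ax.plot_surface(X, Y, Z, cmap="viridis", vmin=0, vmax=1, alpha=0.85,
                    linewidth=0, antialiased=True)

    floor_x, floor_y = _step_outline(curve)
    floor = np.column_stack(
        [np.r_[floor_x, 1.0, 1.0], np.r_[floor_y, 1.0, 0.0],
         np.zeros(floor_x.size + 2)]
    )
    ax.add_collection3d(
        Poly3DCollection([floor], facecolor="0.7", alpha=0.4)
    )
    ax.plot(xs, ys, zs, color="k", lw=1)

    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_zlabel("TDR")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_zlim(0, 1)
    ax.set_title(f"ROC surface (VUS = {metrics.vus(curve):.4g})")
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return output_path


def plot_roc_fdr(
    curve: RocsCurve, b: float = 0.2, output_path: str | Path = "roc_fdr.png"
) -> float:
    """Plot the ROC curve with segments colored by FDR <= b vs FDR > b
    and the FDR-controlled area shaded. Returns the shaded area (the
    FCAUC at level ``b``), which is also printed in the legend.
    """
    output_path = Path(output_path)
    value = metrics.fcauc(curve, b)

    fig, ax = plt.subplots(figsize=(6, 6))
    fpr = np.r_[0.0, curve.fpr]
    tpr = np.r_[0.0, curve.tpr]
    ok = curve.fdr <= b
    for k in range(curve.fpr.size):
        color = "tab:green" if ok[k] else "tab:red"
        ax.plot([fpr[k], fpr[k + 1], fpr[k + 1]],
                [tpr[k], tpr[k], tpr[k + 1]], color=color, lw=2)

    admissible = np.flatnonzero(ok)
    if admissible.size:
        t_star = curve.tpr[admissible[-1]]
        capped = np.minimum(curve.tpr, t_star)
        xs, ys = _step_outline(
            RocsCurve(curve.thresholds, curve.fpr, capped, curve.fdr,
                      curve.n_pos, curve.n_neg)
        )
        ax.fill_betweenx(ys, xs, 1.0, color="tab:blue", alpha=0.25,
                         label=f"FCAUC(b={b:g}) = {value:.4g}")
    else:
        ax.plot([], [], " ", label=f"FCAUC(b={b:g}) = 0")

    ax.plot([], [], color="tab:green", lw=2, label=f"FDR ≤ {b:g}")
    ax.plot([], [], color="tab:red", lw=2, label=f"FDR > {b:g}")
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return value
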