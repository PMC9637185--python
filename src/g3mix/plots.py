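"""Figure emitters: density-over-histogram model plots and class heatmaps.

Model plots show the total mixture PDF in gray over the test histogram,
class 0 in green, classes below the reference in blue and classes above
in red. Heatmaps show per-sample integer class labels on a diverging
palette centered on class 0.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .mixture import MixtureModel  # noqa: E402

__all__ = ["model_plot", "heatmap_plot"]


def _component_color(label: int) -> str:
    if label == 0:
        return "tab:green"
    return "tab:blue" if label < 0 else "tab:red"


def model_plot(values, model: MixtureModel, bins: int = 30, title: str = "", path=None):
    """Test histogram with the fitted mixture PDF and per-class densities."""
    values = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(values, bins=bins, density=True, color="0.85", edgecolor="0.6")
    lo = min(values.min(), min(c.mean - 4 * c.sd for c in model.components))
    hi = max(values.max(), max(c.mean + 4 * c.sd for c in model.components))
    x = np.linspace(lo, hi, 1000)
    for c in model.components:
        ax.plot(x, c.weight * c.pdf(x), color=_component_color(c.label), lw=1.2,
                label=f"class {c.label}")
    ax.plot(x, model.pdf(x), color="0.3", lw=2, label="total")
    ax.set_xlabel("value")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig


def heatmap_plot(matrix, scale: float, title: str = "", path=None):
    """Samples x analytes class heatmap, diverging palette centered on 0."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * matrix.shape[1], 0.5 + 0.12 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-scale, vmax=scale)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("sample")
    fig.colorbar(im, ax=ax, label="class")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
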