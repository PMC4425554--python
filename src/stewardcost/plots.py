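"""Optional matplotlib figures: surface heatmap and PSA histogram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import PSAResult, SensitivityGrid  # noqa: E402

__all__ = ["plot_surface", "plot_psa"]


def plot_surface(grid: SensitivityGrid, path: str | Path) -> None:
    """Heatmap of per-patient net benefit with a dashed €0 contour."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    x, y = grid.axis2.grid, grid.axis1.grid
    mesh = ax.pcolormesh(x, y, grid.values, cmap="RdYlGn", shading="auto")
    fig.colorbar(mesh, ax=ax, label="net benefit (EUR/patient)")
    if (grid.values.min() < 0.0) and (grid.values.max() > 0.0):
        ax.contour(x, y, grid.values, levels=[0.0], colors="black",
                   linestyles="dashed")
    ax.set_xlabel(grid.axis2.parameter_name)
    ax.set_ylabel(grid.axis1.parameter_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_psa(psa: PSAResult, path: str | Path) -> None:
    """Histogram of PSA draws with dashed 2.5/97.5 percentile lines."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.hist(psa.draws, bins=50, color="steelblue", edgecolor="white")
    for q in (psa.summary.p2_5, psa.summary.p97_5):
        ax.axvline(q, color="black", linestyle="dashed")
    ax.axvline(psa.summary.median, color="firebrick")
    ax.set_xlabel("net benefit (EUR/patient)")
    ax.set_ylabel("draws")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
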