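"""Plotting helpers (heatmap, melt curves, shift density).

matplotlib is imported lazily with the Agg backend so the library stays
importable headless.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .fit import BoltzmannFit
from .normalize import MeltCurve
from .shifts import DensityCurve
from .synthetic import boltzmann


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_heatmap(matrix, path: str | Path, cmap: str = "viridis") -> None:
    """Protein x temperature soluble-fraction heatmap (0-1 scale)."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.02 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=1,
                   interpolation="nearest")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel(f"proteins (n={len(matrix)})")
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="soluble fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_density(density: DensityCurve, path: str | Path) -> None:
    """Density of Tm shifts between the treated and vehicle arms."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(density.grid, density.density)
    ax.fill_between(density.grid, density.density, alpha=0.3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("dTm (degC, treated - vehicle)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_melt_fit(curves: list[MeltCurve], fits: list[BoltzmannFit],
                  path: str | Path) -> None:
    """Observed points and fitted sigmoids for one protein, both arms."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"vehicle": "tab:blue", "treated": "tab:red"}
    for curve, fit in zip(curves, fits):
        color = colors.get(curve.condition, "tab:grey")
        ax.plot(curve.temperatures, curve.fractions, "o", color=color, ms=4,
                label=f"{curve.condition} rep{curve.replicate}")
        grid = np.linspace(curve.temperatures.min(), curve.temperatures.max(), 200)
        ax.plot(grid, boltzmann(grid, fit.params.midpoint, fit.params.slope,
                                fit.params.plateau), color=color, lw=1)
        if fit.tm_defined:
            ax.axvline(fit.tm, color=color, lw=0.6, ls=":")
    ax.axhline(0.5, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("soluble fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
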