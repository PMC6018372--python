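"""Contour rendering of Z-averaged strain maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .strain import PlanarStrainMaps

__all__ = ["plot_strain_maps"]


def plot_strain_maps(
    planar: PlanarStrainMaps,
    path: str | Path,
    measures: tuple[str, ...] = ("E_XX", "E_YY", "E_XY", "E_max", "Gamma_max"),
) -> None:
    """Write a panel of filled-contour maps, one per strain measure.

    Invalid columns render blank. Axes are in micrometers, X horizontal
    (nasal-temporal), Y vertical (inferior-superior).
    """
    measures = tuple(m for m in measures if m in planar.maps)
    fig, axes = plt.subplots(1, len(measures), figsize=(3.2 * len(measures), 3.2), squeeze=False)
    X, Y = np.meshgrid(*planar.axes, indexing="ij")
    for ax, name in zip(axes[0], measures):
        data = planar.maps[name]
        finite = np.isfinite(data)
        if finite.any():
            lim = np.nanmax(np.abs(data))
            cs = ax.contourf(X, Y, np.where(finite, data, np.nan), levels=21, cmap="RdBu_r",
                             vmin=-lim, vmax=lim)
            fig.colorbar(cs, ax=ax, shrink=0.8)
        ax.set_title(name)
        ax.set_aspect("equal")
        ax.set_xlabel("X (um)")
    axes[0][0].set_ylabel("Y (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
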