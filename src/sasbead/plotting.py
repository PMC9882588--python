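"""Plot helpers: 2-D projections of bead models and model-comparison overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .noise import SimulatedData
from .pairdist import PairDistribution, ScatteringCurve
from .subunits import PointCloud

__all__ = ["plot_projections", "plot_pr_overlay", "plot_iq_overlay"]

_PLANES = (("x", "y", 0, 1), ("x", "z", 0, 2), ("y", "z", 1, 2))


def plot_projections(cloud: PointCloud, path) -> None:
    """Three scatter plots (xy, xz, yz) colored by contrast sign.

    Red: positive contrast, green: negative, grey: zero — the conventional
    rendering of multi-contrast bead models.
    """
    colors = np.where(
        cloud.weights > 0, "crimson", np.where(cloud.weights < 0, "seagreen", "grey")
    )
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.5))
    for ax, (nx, ny, ix, iy) in zip(axes, _PLANES):
        ax.scatter(cloud.positions[:, ix], cloud.positions[:, iy], s=2, c=colors)
        ax.set_xlabel(f"{nx} [Å]")
        ax.set_ylabel(f"{ny} [Å]")
        ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pr_overlay(pds: list[PairDistribution], labels: list[str], path) -> None:
    """Overlay of max-normalized p(r) curves."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for pd, label in zip(pds, labels):
        r, p = pd.export_arrays()
        ax.plot(r, p, label=label)
    ax.set_xlabel("r [Å]")
    ax.set_ylabel("p(r)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_iq_overlay(
    curves: list[ScatteringCurve],
    datas: list[SimulatedData],
    labels: list[str],
    path,
    offset: float = 100.0,
) -> None:
    """Log-log overlay of I(q) and simulated data; model 2 offset ×offset."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, (curve, data, label) in enumerate(zip(curves, datas, labels)):
        fac = offset**i
        ax.errorbar(
            data.q, data.i_sim * fac, yerr=data.sigma * fac,
            fmt=".", ms=2, alpha=0.4, lw=0.5,
        )
        suffix = f" (×{fac:g})" if fac != 1 else ""
        ax.plot(curve.q, curve.I * fac, label=label + suffix)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("q [Å$^{-1}$]")
    ax.set_ylabel("I(q)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
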