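"""Optional matplotlib views of sweeps and rate-plane scans."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .param_scan import FieldSweep, ScanGrid

__all__ = ["plot_field_sweep", "plot_kr_scan"]


def plot_field_sweep(sweep: FieldSweep, path=None, as_percent: bool = True):
    """Φ_S versus field strength (log-x), optionally saved to ``path``."""
    fig, ax = plt.subplots(figsize=(6, 4))
    y = sweep.phi_values * (100 if as_percent else 1)
    ax.plot(sweep.B_values, y, lw=1.2)
    ax.set_xscale("log")
    ax.set_xlabel("B (mT)")
    ax.set_ylabel(r"$\Phi_S$ (%)" if as_percent else r"$\Phi_S$")
    ax.set_title(
        f"{sweep.label}: k={sweep.kinetics.k:.2g}/s, r={sweep.kinetics.r:.2g}/s"
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_kr_scan(grid: ScanGrid, path=None):
    """Heatmap of the yield ratio S in the k–r plane (log–log axes)."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    pcm = ax.pcolormesh(
        grid.r_values, grid.k_values, grid.S_matrix, shading="auto", cmap="viridis"
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("r (s$^{-1}$)")
    ax.set_ylabel("k (s$^{-1}$)")
    ax.set_title(
        f"{grid.label}: S = $\\Phi_S$({grid.Bexp:g} mT)/$\\Phi_S$({grid.B0:g} mT)"
    )
    fig.colorbar(pcm, ax=ax, label="S")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
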