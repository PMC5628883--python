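"""Plotting helpers: trajectories, response surfaces, isobolograms.

All functions take an optional ``ax`` and return the matplotlib Axes, so they
compose into figure grids.
"""

from __future__ import annotations

import numpy as np

from .network import Trajectory
from .synergy import Isobologram, SynergySurface

__all__ = ["plot_trajectory", "plot_surface", "plot_isobologram"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: Trajectory, species=("ppERK", "DUSP", "SPRY"),
                    normalise: bool = True, ax=None):
    """Time courses of selected species, optionally normalised to t=0."""
    ax = _get_ax(ax)
    for name in species:
        y = traj[name]
        if normalise and y[0] > 0:
            y = y / y[0]
        ax.plot(traj.times, y, label=name)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("level (fraction of baseline)" if normalise
                  else "concentration (nM)")
    ax.legend(frameon=False)
    return ax


def plot_surface(surface: SynergySurface, which: str = "excess", ax=None):
    """Heat map of the observed/expected/excess matrix over the dose lattice."""
    ax = _get_ax(ax)
    mat = {"observed": surface.observed, "expected": surface.expected,
           "excess": surface.excess}[which]
    vmax = float(np.max(np.abs(mat))) if which == "excess" else 1.0
    kwargs = (dict(cmap="RdBu_r", vmin=-vmax, vmax=vmax) if which == "excess"
              else dict(cmap="viridis", vmin=0.0, vmax=1.0))
    im = ax.imshow(mat.T, origin="lower", aspect="auto", **kwargs)
    ax.figure.colorbar(im, ax=ax, label=which)
    ax.set_xticks(range(len(surface.grid.doses_a)))
    ax.set_xticklabels([f"{d:g}" for d in surface.grid.doses_a], rotation=90)
    ax.set_yticks(range(len(surface.grid.doses_b)))
    ax.set_yticklabels([f"{d:g}" for d in surface.grid.doses_b])
    ax.set_xlabel("drug A dose (nM)")
    ax.set_ylabel("drug B dose (nM)")
    return ax


def plot_isobologram(iso: Isobologram, ax=None):
    """Observed constant-effect contour vs the straight Loewe reference line."""
    ax = _get_ax(ax)
    if not iso.empty:
        ax.plot(iso.points[:, 0], iso.points[:, 1], "o-", color="tab:blue",
                label=f"observed {iso.level:.0%} isobole")
    if iso.reference is not None:
        ax.plot(iso.reference[:, 0], iso.reference[:, 1], "-", color="tab:red",
                label="Loewe additivity")
    ax.set_xlabel("drug A dose (nM)")
    ax.set_ylabel("drug B dose (nM)")
    ax.legend(frameon=False)
    return ax
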