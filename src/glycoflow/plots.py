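"""Rendered figures for the standard analyses (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_energy_map", "plot_velocity_profile", "plot_abx_overlay"]


def plot_energy_map(energy_map, path=None, title: str = ""):
    """Heat map of a Boltzmann energy grid (kcal/mol); masked bins blank."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    e = energy_map.edges
    im = ax.pcolormesh(e, e, energy_map.energies.T, cmap="viridis_r")
    ax.set_xlabel(f"{energy_map.axis_names[0]} (deg)")
    ax.set_ylabel(f"{energy_map.axis_names[1]} (deg)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="energy (kcal/mol)")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_velocity_profile(profiles: dict, path=None, solute_range=None):
    """Overlay slab velocity profiles per condition; dotted bulk means."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, prof in profiles.items():
        occ = prof.counts > 0
        line, = ax.plot(prof.centers[occ], prof.means[occ], label=label)
        ax.axhline(prof.bulk_mean, ls=":", color=line.get_color(), lw=1)
    if solute_range is not None:
        ax.axvspan(*solute_range, alpha=0.12, color="grey",
                   label="solute range")
    ax.set_xlabel("y (Å)")
    ax.set_ylabel(f"slab mean v ({next(iter(profiles.values())).unit})")
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_abx_overlay(distributions, path=None):
    """∠ABx histograms per condition for one residue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for dist in distributions:
        centers = 0.5 * (dist.edges[:-1] + dist.edges[1:])
        ax.plot(centers, dist.densities, label=dist.condition or "run")
    ax.set_xlabel(f"∠AB{distributions[0].residue} (deg)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
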