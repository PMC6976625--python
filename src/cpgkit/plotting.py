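"""Figure export: phase diagrams, correlograms, density heat-maps, frequency densities."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .rhythm import Correlogram, PhaseSample

__all__ = [
    "plot_phase_diagram",
    "plot_correlogram",
    "plot_frequency_density",
    "plot_density_map",
]


def plot_phase_diagram(ps: PhaseSample, stats: dict | None = None, ax=None):
    """Circular scatter of per-cycle phases with the mean resultant vector."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.deg2rad(ps.phases)
    ax.plot(theta, np.ones_like(theta), "o", alpha=0.4, ms=4)
    if stats and not stats.get("mean_undefined", False):
        mu = np.deg2rad(stats["mean_deg"])
        ax.plot([mu, mu], [0.0, stats["R"]], color="C3", lw=2)
        ax.plot([mu], [stats["R"]], "o", color="C3", ms=6)
    ax.set_theta_zero_location("E")
    ax.set_rticks([])
    ax.set_title("/".join(ps.pair), fontsize=10)
    return ax


def plot_correlogram(corr: Correlogram, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(corr.lags, corr.coefficients, lw=1)
    ax.axvline(0, color="k", lw=0.5)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("lag [s]")
    ax.set_ylabel("correlation")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title("/".join(corr.pair), fontsize=10)
    return ax


def plot_frequency_density(modes: dict, ax=None, label=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(modes["grid_hz"], modes["density"], lw=1.5, label=label)
    for m in modes["modes_hz"]:
        ax.axvline(m, color="C3", lw=0.8, ls="--")
    ax.set_xlabel("cycle frequency [Hz]")
    ax.set_ylabel("density (peak = 1)")
    return ax


def plot_density_map(dm: dict, ax=None):
    """Soma-density heat-map over the unit (ML, DV) square."""
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(
        dm["map2d"],
        origin="lower",
        extent=(0, 1, 0, 1),
        aspect="equal",
        cmap="inferno",
    )
    ax.set_xlabel("ML (fraction of hemicord width)")
    ax.set_ylabel("DV (fraction of cord height)")
    return ax


def save_figure(ax_or_fig, path: str | Path) -> Path:
    fig = getattr(ax_or_fig, "figure", ax_or_fig)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
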