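"""Basic diagnostic figures (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .crystallization import NormalizedSeries
from .dielectric import HNResults
from .relaxation import RelaxationMap, StickelResult, VFTResults

__all__ = ["plot_hn_fit", "plot_relaxation_map", "plot_stickel", "plot_kinetics"]


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    return plt.subplots()[1]


def plot_hn_fit(res: HNResults, ax=None):
    """Measured loss spectrum with the fitted HN + conductivity curve."""
    ax = _ax(ax)
    spec = res.model.spectrum
    ax.loglog(spec.frequency, spec.eps_imag, "o", ms=3, label="data")
    f = np.logspace(
        np.log10(spec.frequency[0]), np.log10(spec.frequency[-1]), 400
    )
    ax.loglog(f, res.predict(f)[1], "-", label="HN fit")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(r"$\varepsilon''$")
    ax.set_title(f"T = {spec.temperature:.1f} K")
    ax.legend()
    return ax


def plot_relaxation_map(rmap: RelaxationMap, res: VFTResults | None = None, ax=None):
    """log10 tau_alpha vs 1000/T with an optional VFT curve."""
    ax = _ax(ax)
    ax.plot(1000.0 / rmap.temperature, np.log10(rmap.tau_alpha), "o", ms=4,
            label=rmap.sample_label or "data")
    if res is not None:
        t = np.linspace(rmap.temperature.min(), rmap.temperature.max(), 300)
        ax.plot(1000.0 / t, np.log10(res.tau(t)), "-", label="VFT")
    ax.set_xlabel("1000 / T (K$^{-1}$)")
    ax.set_ylabel(r"$\log_{10}\,\tau_\alpha$ (s)")
    ax.legend()
    return ax


def plot_stickel(sr: StickelResult, ax=None):
    """Stickel transform with fitted segments and crossover marker."""
    ax = _ax(ax)
    ax.plot(sr.temperature, sr.phi, "o", ms=4, label="transform")
    for slope, intercept, (lo, hi) in sr.segments:
        t = np.linspace(lo, hi, 50)
        ax.plot(t, slope * t + intercept, "-")
    if sr.t_cross is not None:
        ax.axvline(sr.t_cross, ls="--", color="k", label=f"T$_{{cross}}$ = {sr.t_cross:.0f} K")
    ax.set_xlabel("T (K)")
    ax.set_ylabel(r"$[-d\log_{10}\tau_\alpha/dT]^{-1/2}$")
    ax.legend()
    return ax


def plot_kinetics(ns: NormalizedSeries, ax=None):
    """Normalized crystallization curve with the default threshold levels."""
    ax = _ax(ax)
    ax.plot(ns.time / 3600.0, ns.eps_norm, "o-", ms=3)
    for level, ls in [(0.05, ":"), (0.5, "--"), (0.95, ":")]:
        ax.axhline(level, ls=ls, color="gray", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(r"$\varepsilon'_N$")
    return ax
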