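"""Synthetic instrument data with known ground truth.

Every input the analysis chain consumes can be generated here — DSC
heating scans with solidus/liquidus structure and a glass-transition step,
Havriliak–Negami loss spectra whose peak time follows a one- or two-regime
VFT law, and sigmoidal static-permittivity crystallization decays — so the
full pipeline is testable without instrument data.  Each generator returns
the data object *and* a ground-truth dictionary (written as a JSON sidecar
by the I/O layer) that round-trip tests consume.

Modelling choices (see docs/methods.md): the mixture Tg of a synthetic DSC
trace follows a Gordon–Taylor rule with unit interaction parameter (a
stand-in, not a fitted law); melting endotherms have a linear leading edge
and exponential tail so the tangent-construction onset is exact by
construction; dc conductivity in synthetic spectra tracks 1/τ_α
(Debye–Stokes–Einstein-type coupling) with a configurable amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .components import PureComponent, weight_to_mole
from .crystallization import CrystallizationSeries
from .dielectric import DielectricSpectrum, HNParameters, hn_model, tau_alpha_from_hn
from .dsc import Thermogram
from .phase import binary_eutectic, svl_liquidus, ternary_eutectic
from .presets import CRYSTALLIZATION_PRESETS
from .relaxation import VFTParameters, vft_tau

__all__ = [
    "GeneratorConfig",
    "make_dsc",
    "make_bds_series",
    "make_crystallization",
    "make_crystallization_preset",
]

NoiseModel = Literal["none", "gaussian-additive", "multiplicative"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducibility and noise settings shared by all generators.

    ``noise_scale`` is relative: for additive noise it multiplies the
    signal's characteristic amplitude, for multiplicative noise it is the
    per-point relative standard deviation.  ``noise_model=None`` selects
    each generator's default (additive for DSC and permittivity decays,
    multiplicative for dielectric loss).
    """

    seed: int = 0
    noise_model: NoiseModel | None = None
    noise_scale: float | None = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolved(self, default_model: NoiseModel, default_scale: float):
        model = self.noise_model if self.noise_model is not None else default_model
        scale = self.noise_scale if self.noise_scale is not None else default_scale
        return model, scale


def _apply_noise(
    y: np.ndarray,
    rng: np.random.Generator,
    model: NoiseModel,
    scale: float,
    amplitude: float,
) -> np.ndarray:
    if model == "none" or scale == 0:
        return y
    if model == "gaussian-additive":
        return y + rng.normal(0.0, scale * amplitude, size=y.shape)
    if model == "multiplicative":
        return y * (1.0 + rng.normal(0.0, scale, size=y.shape))
    raise ValueError(f"unknown noise model {model!r}")


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

def _melt_peak(
    t: np.ndarray, onset: float, peak: float, height: float, tail: float
) -> np.ndarray:
    """Endotherm with a linear leading edge (onset → peak) and exponential
    tail; the tangent-construction onset equals ``onset`` exactly."""
    y = np.zeros_like(t)
    rise = (t >= onset) & (t <= peak)
    y[rise] = height * (t[rise] - onset) / (peak - onset)
    decay = t > peak
    y[decay] = height * np.exp(-(t[decay] - peak) / tail)
    return y


def make_dsc(
    components: Sequence[PureComponent],
    weight_fractions: Sequence[float],
    *,
    rate: float = 10.0,
    cfg: GeneratorConfig = GeneratorConfig(),
    t_range: tuple[float, float] | None = None,
    t_step: float = 0.05,
    tg_step_height: float = 0.2,
    tg_width: float = 2.0,
    peak_height: float = 10.0,
    rate_lag: float = 0.05,
    endotherm_resolve_tol: float = 1.0,
) -> tuple[Thermogram, dict]:
    """Synthetic heating scan of a physical drug mixture.

    Constructed as baseline + glass-transition step (center from a
    Gordon–Taylor mixing rule over the component amorphous Tg values)
    + one melting endotherm per expected event: the eutectic melt at T_e
    and, for every component whose SVL liquidus at this composition lies
    more than ``endotherm_resolve_tol`` K above T_e, a dissolution
    endotherm peaking at that branch temperature.  Areas are proportional
    to the melting mass fractions.  All events shift upward by
    ``rate_lag * rate`` K, emulating instrument thermal lag.

    Returns ``(thermogram, ground_truth)``.
    """
    w = np.asarray(weight_fractions, dtype=float)
    masses = [c.molar_mass for c in components]
    x = weight_to_mole(w, masses)

    if len(components) == 2:
        xe, te = binary_eutectic(components[0], components[1])
    elif len(components) == 3:
        *_, te = ternary_eutectic(*components)
    else:
        raise ValueError("make_dsc supports 2 or 3 components")

    lag = rate_lag * rate
    branch = np.array([svl_liquidus(xi, c) for xi, c in zip(x, components)])
    above = branch > te + endotherm_resolve_tol

    # Gordon-Taylor mixture Tg, unit interaction parameter (see module docstring)
    tgs = np.array([c.glass_tg if c.glass_tg is not None else np.nan for c in components])
    if np.any(np.isnan(tgs)):
        tg_mix = None
    else:
        tg_mix = float(np.sum(w * tgs) / np.sum(w))

    events = [
        {"onset": te + lag, "peak": te + lag + 1.5, "area_weight": 1.0, "kind": "eutectic"}
    ]
    for flag, tb, wi, c in zip(above, branch, w, components):
        if flag:
            events.append(
                {
                    "onset": tb + lag - 1.5,
                    "peak": tb + lag,
                    "area_weight": float(wi),
                    "kind": f"melt_{c.name}",
                }
            )
    events.sort(key=lambda e: e["peak"])

    if t_range is None:
        lo = (min(tg_mix - 40.0, te - 30.0) if tg_mix is not None else te - 40.0)
        hi = float(branch.max() + 25.0)
        t_range = (lo, hi)
    t = np.arange(t_range[0], t_range[1] + t_step, t_step)

    y = 0.001 * (t - t[0])  # gentle instrument baseline drift
    if tg_mix is not None and tg_mix > t[0] + 5 * tg_width:
        y = y + tg_step_height / (1.0 + np.exp(-(t - tg_mix) / (tg_width / 4.0)))
    for ev in events:
        y = y + _melt_peak(
            t, ev["onset"], ev["peak"], peak_height * max(ev["area_weight"], 0.05), 1.0
        )

    model, scale = cfg.resolved("gaussian-additive", 0.01)
    y = _apply_noise(y, cfg.rng(), model, scale, amplitude=peak_height)

    truth = {
        "tg_mix": tg_mix,
        "eutectic_temperature": float(te),
        "events": events,
        "endotherm_count": len(events),
        "rate": rate,
        "rate_lag": lag,
    }
    return (
        Thermogram(temperature=t, heat_flow=y, heating_rate=rate),
        truth,
    )


# ---------------------------------------------------------------------------
# Broadband dielectric spectra
# ---------------------------------------------------------------------------

def _tau_alpha_of_t(
    temp: float,
    vft1: VFTParameters,
    vft2: VFTParameters | None,
    t_cross: float | None,
) -> float:
    """Two-regime VFT: VFT1 below the crossover, VFT2 above it."""
    if vft2 is not None and t_cross is not None and temp > t_cross:
        return float(vft_tau(temp, vft2))
    return float(vft_tau(temp, vft1))


def make_bds_series(
    *,
    vft1: VFTParameters,
    vft2: VFTParameters | None = None,
    t_cross: float | None = None,
    temperatures: Sequence[float],
    a: float = 0.8,
    b: float = 0.6,
    delta_eps: float = 8.0,
    eps_inf: float = 3.0,
    cond_coupling: float = 0.0,
    freq_range: tuple[float, float] = (1e-1, 1e7),
    points_per_decade: int = 10,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[DielectricSpectrum], dict]:
    """Synthetic HN loss spectra whose peak time follows a VFT law.

    For each temperature the HN time is set so that the loss-peak
    relaxation time equals the VFT-prescribed τ_α (inverting the peak-time
    conversion, which depends only on the shape exponents).  The dc
    conductivity is σ_dc = ε0·Δε·cond_coupling/τ_α, i.e. it follows the
    same super-Arrhenius activation as the structural relaxation; set
    ``cond_coupling=0`` for conductivity-free spectra.

    Returns ``(spectra, ground_truth)``.
    """
    from scipy.constants import epsilon_0

    shape_factor = tau_alpha_from_hn(
        HNParameters(eps_inf=eps_inf, delta_eps=delta_eps, tau_hn=1.0, a=a, b=b)
    )
    n_dec = np.log10(freq_range[1] / freq_range[0])
    freq = np.logspace(
        np.log10(freq_range[0]),
        np.log10(freq_range[1]),
        int(round(n_dec * points_per_decade)) + 1,
    )
    rng = cfg.rng()
    model, scale = cfg.resolved("multiplicative", 0.005)

    spectra: list[DielectricSpectrum] = []
    truth_rows = []
    for temp in temperatures:
        tau_a = _tau_alpha_of_t(temp, vft1, vft2, t_cross)
        p = HNParameters(
            eps_inf=eps_inf,
            delta_eps=delta_eps,
            tau_hn=tau_a / shape_factor,
            a=a,
            b=b,
            sigma_dc=epsilon_0 * delta_eps * cond_coupling / tau_a,
        )
        er, ei = hn_model(freq, p)
        ei = _apply_noise(ei, rng, model, scale, amplitude=float(ei.max()))
        er = _apply_noise(er, rng, model, scale, amplitude=float(er.max()))
        spectra.append(
            DielectricSpectrum(
                frequency=freq, eps_real=er, eps_imag=np.abs(ei), temperature=float(temp)
            )
        )
        truth_rows.append(
            {
                "temperature": float(temp),
                "tau_alpha": tau_a,
                "tau_hn": p.tau_hn,
                "sigma_dc": p.sigma_dc,
            }
        )
    truth = {
        "a": a,
        "b": b,
        "delta_eps": delta_eps,
        "eps_inf": eps_inf,
        "vft1": {
            "log10_tau_inf": vft1.log10_tau_inf,
            "B": vft1.B,
            "T0_vogel": vft1.T0_vogel,
        },
        "vft2": None
        if vft2 is None
        else {
            "log10_tau_inf": vft2.log10_tau_inf,
            "B": vft2.B,
            "T0_vogel": vft2.T0_vogel,
        },
        "t_cross": t_cross,
        "points": truth_rows,
    }
    return spectra, truth


# ---------------------------------------------------------------------------
# Isothermal crystallization
# ---------------------------------------------------------------------------

def make_crystallization(
    *,
    t_half: float,
    avrami_n: float = 3.0,
    eps0: float = 10.0,
    epsinf: float = 4.0,
    duration: float | None = None,
    step: float = 600.0,
    temperature: float = 300.0,
    label: str = "",
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[CrystallizationSeries, dict]:
    """Sigmoidal ε′(t) decay with Avrami kinetics and known half-life.

    ε′(t) = ε∞ + (ε0 − ε∞)·exp(−ln2·(t/t_half)^n), sampled every ``step``
    seconds (600 s emulates the instrument cadence) for ``duration``
    seconds (default: long enough for ~99.9% conversion).
    """
    if duration is None:
        # time to 99.9% conversion, padded
        duration = t_half * (np.log(1e3) / np.log(2.0)) ** (1.0 / avrami_n) * 1.3
    t = np.arange(0.0, duration + step, step)
    eps = epsinf + (eps0 - epsinf) * np.exp(-np.log(2.0) * (t / t_half) ** avrami_n)
    model, scale = cfg.resolved("gaussian-additive", 0.005)
    eps = _apply_noise(eps, cfg.rng(), model, scale, amplitude=eps0 - epsinf)
    truth = {
        "t_half": float(t_half),
        "avrami_n": float(avrami_n),
        "eps0": float(eps0),
        "epsinf": float(epsinf),
        "step": float(step),
        "temperature": float(temperature),
    }
    return (
        CrystallizationSeries(
            time=t, eps_static=eps, temperature=temperature, sample_label=label
        ),
        truth,
    )


def make_crystallization_preset(
    name: str, *, avrami_n: float = 3.0, cfg: GeneratorConfig = GeneratorConfig()
) -> tuple[CrystallizationSeries, dict]:
    """Generate a decay from a named reported-kinetics preset.

    Available names: ``"EZB"``, ``"FEN"``, ``"SVT"``, ``"5.3/10.5/84.2"``
    (see :mod:`pharmglass.presets`).
    """
    preset = CRYSTALLIZATION_PRESETS[name]
    return make_crystallization(
        t_half=preset.half_life_s,
        avrami_n=avrami_n,
        temperature=preset.temperature,
        label=name,
        cfg=cfg,
    )
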