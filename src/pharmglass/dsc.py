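"""Calorimetric feature extraction from DSC thermograms.

Extracts the observables a formulation scientist reads off a heating scan:
melting endotherms (onset by the tangent construction, peak maximum,
enthalpy by linear-baseline integration), the glass transition as the
midpoint of the heat-capacity step, and the solidus/liquidus assignment
for mixtures (solidus = onset of the first endotherm, liquidus = peak
maximum of the last one).

Heat flow is handled internally in the endotherm-up convention; instrument
traces recorded endo-down are flipped on construction via ``endo_up=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Thermogram",
    "ThermalEvent",
    "detect_endotherms",
    "glass_transition_midpoint",
    "solidus_liquidus",
    "GlassTransitionNotFound",
]


class GlassTransitionNotFound(RuntimeError):
    """No heat-capacity step detected in the trace."""


@dataclass(frozen=True)
class Thermogram:
    """Temperature-indexed heat-flow trace.

    ``heat_flow`` is stored endo-up regardless of the instrument convention;
    pass ``endo_up=False`` for endo-down recordings and the trace is negated.
    """

    temperature: np.ndarray  # K, strictly increasing
    heat_flow: np.ndarray  # signal units, endo-up after construction
    heating_rate: float  # K/min
    sample_mass: float | None = None  # mg
    endo_up: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        h = np.asarray(self.heat_flow, dtype=float)
        if t.ndim != 1 or t.shape != h.shape:
            raise ValueError("temperature and heat_flow must be equal-length 1-D arrays")
        if t.size < 50:
            raise ValueError(f"thermogram too short ({t.size} points, need >= 50)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if not self.endo_up:
            h = -h
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "heat_flow", h)
        object.__setattr__(self, "endo_up", True)


@dataclass(frozen=True)
class ThermalEvent:
    """One detected thermal event on a heating scan."""

    kind: Literal["endotherm", "glass_transition"]
    onset: float  # K
    peak_or_midpoint: float  # K
    enthalpy: float | None = None  # J/g for endotherms when mass known, else area

    def __post_init__(self) -> None:
        if self.onset > self.peak_or_midpoint + 1e-9:
            raise ValueError("onset must not exceed peak/midpoint temperature")
        if self.enthalpy is not None and self.enthalpy < 0:
            raise ValueError("enthalpy must be >= 0")


def _detrended_noise_scale(y: np.ndarray) -> float:
    """Robust noise scale: MAD of the second difference (removes trends/peaks)."""
    d2 = np.diff(y, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    # second difference of iid noise has variance 6 sigma^2
    return float(mad * 1.4826 / np.sqrt(6.0)) if mad > 0 else 0.0


def _onset_by_tangents(
    t: np.ndarray, y: np.ndarray, i_peak: int, i_left: int, i_base_lo: int
) -> float:
    """Onset = intersection of the pre-peak baseline tangent with the
    leading-edge tangent (line fitted between 25% and 75% of peak height,
    the noise-robust variant of the steepest-slope construction)."""
    # baseline tangent: linear fit over the stretch before the peak foot
    lo = max(0, min(i_base_lo, i_left - 2))
    if i_left - lo < 2:
        lo, i_left_fit = max(0, i_left - 2), max(2, i_left)
    else:
        i_left_fit = i_left
    pb = np.polyfit(t[lo : i_left_fit + 1], y[lo : i_left_fit + 1], 1)

    # leading-edge tangent on the 25-75% height band above the baseline
    edge = slice(i_left, i_peak + 1)
    excess = y[edge] - np.polyval(pb, t[edge])
    e_pk = excess[-1]
    if e_pk <= 0:
        return float(t[i_left])
    band = (excess >= 0.25 * e_pk) & (excess <= 0.75 * e_pk)
    # restrict to the contiguous run ending at the peak side
    idx = np.flatnonzero(band)
    if idx.size >= 2:
        pt = np.polyfit(t[edge][idx], y[edge][idx], 1)
    else:  # degenerate edge: fall back to the steepest-point tangent
        dy = np.gradient(y[edge], t[edge])
        k = int(np.argmax(dy))
        if dy[k] <= 0:
            return float(t[i_left])
        pt = np.array([dy[k], y[edge][k] - dy[k] * t[edge][k]])
    if pt[0] <= pb[0]:
        return float(t[i_left])
    t_onset = (pt[1] - pb[1]) / (pb[0] - pt[0])
    return float(np.clip(t_onset, t[lo], t[i_peak]))


def detect_endotherms(
    tg: Thermogram,
    prominence_threshold: float | None = None,
    *,
    smooth_window: float = 1.0,
) -> list[ThermalEvent]:
    """Locate melting endotherms and characterise each.

    The trace is Savitzky–Golay smoothed over ``smooth_window`` K (set 0 to
    disable) and peaks are found by local-extremum search with a prominence
    filter (default: 5x the robust noise scale of the detrended raw trace).
    For each peak the onset comes from the tangent construction and the
    enthalpy from trapezoidal integration above a linear baseline spanning
    the peak base, converted to J/g when the sample mass is known (heat
    flow in mW, rate in K/min).  An empty list — not an error — is
    returned when nothing rises above the threshold.
    """
    t, y_raw = tg.temperature, tg.heat_flow
    if prominence_threshold is None:
        noise = _detrended_noise_scale(y_raw)
        span = float(np.ptp(y_raw))
        prominence_threshold = max(5.0 * noise, 1e-3 * span) if span > 0 else 1.0
    dt = float(np.median(np.diff(t)))
    win = int(round(smooth_window / dt)) | 1 if smooth_window > 0 else 0
    if win >= 5:
        y = signal.savgol_filter(y_raw, win, 2)
    else:
        y = y_raw
    peaks, _ = signal.find_peaks(y, prominence=prominence_threshold, width=1)
    if peaks.size == 0:
        return []
    # local feet at 97% of prominence height (find_peaks bases can extend
    # across unrelated structure such as the glass-transition step)
    _, _, lips, rips = signal.peak_widths(y, peaks, rel_height=0.97)
    n_base = max(5, int(round(2.0 / dt)) if dt > 0 else 5)
    events: list[ThermalEvent] = []
    for k, p in enumerate(peaks):
        lb = max(int(np.floor(lips[k])), 0)
        rb = min(int(np.ceil(rips[k])), t.size - 1)
        # clip at the inter-peak minima so neighbouring peaks never swallow
        # each other's baseline stretch
        prev_sep = 0
        if k > 0:
            prev_sep = peaks[k - 1] + int(np.argmin(y[peaks[k - 1] : p + 1]))
            lb = max(lb, prev_sep)
        if k + 1 < peaks.size:
            sep = p + int(np.argmin(y[p : peaks[k + 1] + 1]))
            rb = min(rb, sep)
        onset = _onset_by_tangents(
            t, y, int(p), lb, max(lb - n_base, prev_sep)
        )
        baseline = np.interp(t[lb : rb + 1], [t[lb], t[rb]], [y[lb], y[rb]])
        area_signal = np.trapezoid(y[lb : rb + 1] - baseline, t[lb : rb + 1])
        area_signal = max(float(area_signal), 0.0)
        # mW * K / (K/min) = mW * min = mJ * 60; per mg -> J/g
        if tg.sample_mass:
            enthalpy = area_signal / tg.heating_rate * 60.0 / tg.sample_mass
        else:
            enthalpy = area_signal
        events.append(
            ThermalEvent(
                kind="endotherm",
                onset=min(onset, float(t[p])),
                peak_or_midpoint=float(t[p]),
                enthalpy=enthalpy,
            )
        )
    events.sort(key=lambda e: e.peak_or_midpoint)
    return events


def glass_transition_midpoint(
    tg: Thermogram,
    *,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
) -> float:
    """Glass transition temperature as the heat-capacity-step midpoint.

    Pre- and post-transition baselines are fitted linearly on the given
    temperature windows (defaults: first and last 25% of the scan) and the
    midpoint is the temperature at which the trace crosses half the step
    height between the extrapolated baselines.

    Raises :class:`GlassTransitionNotFound` when no step is detectable.
    """
    t, y = tg.temperature, tg.heat_flow
    if pre_window is None:
        pre_window = (t[0], t[0] + 0.25 * (t[-1] - t[0]))
    if post_window is None:
        post_window = (t[-1] - 0.25 * (t[-1] - t[0]), t[-1])
    pre_mask = (t >= pre_window[0]) & (t <= pre_window[1])
    post_mask = (t >= post_window[0]) & (t <= post_window[1])
    if pre_mask.sum() < 3 or post_mask.sum() < 3:
        raise GlassTransitionNotFound("baseline windows contain too few points")
    pb = np.polyfit(t[pre_mask], y[pre_mask], 1)
    qb = np.polyfit(t[post_mask], y[post_mask], 1)

    base_lo = np.polyval(pb, t)
    base_hi = np.polyval(qb, t)
    step = base_hi - base_lo
    mid_scale = float(np.median(step))
    noise = _detrended_noise_scale(y)
    if mid_scale <= max(5.0 * noise, 1e-12):
        raise GlassTransitionNotFound("no resolvable heat-capacity step")

    half = base_lo + 0.5 * step
    search = (t > pre_window[1]) & (t < post_window[0])
    idx = np.flatnonzero(search)
    if idx.size < 2:
        raise GlassTransitionNotFound("no interior region between baseline windows")
    diff = y[idx] - half[idx]
    crossings = np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)
    if crossings.size == 0:
        # allow a touch (zero) crossing
        zero = np.flatnonzero(diff == 0)
        if zero.size:
            return float(t[idx[zero[0]]])
        raise GlassTransitionNotFound("trace never crosses the half-step level")
    k = idx[crossings[0]]
    # linear interpolation between bracketing samples
    d0, d1 = y[k] - half[k], y[k + 1] - half[k + 1]
    frac = d0 / (d0 - d1)
    return float(t[k] + frac * (t[k + 1] - t[k]))


def solidus_liquidus(
    events: Sequence[ThermalEvent],
) -> tuple[float, float, bool]:
    """Assign solidus and liquidus temperatures from detected endotherms.

    Solidus is the onset of the first endotherm; liquidus the peak-maximum
    temperature of the last.  A single event means the composition melts as
    a eutectic: equal values are returned with the third element
    (``eutectic_like``) set True.
    """
    endos = sorted(
        (e for e in events if e.kind == "endotherm"),
        key=lambda e: e.peak_or_midpoint,
    )
    if not endos:
        raise ValueError("need at least one endotherm")
    if len(endos) == 1:
        e = endos[0]
        return e.onset, e.onset, True
    return endos[0].onset, endos[-1].peak_or_midpoint, False
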