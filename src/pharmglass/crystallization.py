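"""Isothermal crystallization kinetics from static-permittivity decays.

As an amorphous sample devitrifies, its static permittivity ε′ drops from
the supercooled-liquid value ε′(0) to the crystalline value ε′(∞).  The
degree of conversion is tracked by the normalized real permittivity

    ε′_N(t) = (ε′(0) − ε′(t)) / (ε′(0) − ε′(∞))

which runs from 0 (fully amorphous) to 1 (fully crystalline).  From the
normalized curve the onset, half-life and endset times are read off as
threshold crossings (defaults 0.05 / 0.5 / 0.95, configurable).

An Avrami fit (ε′_N = 1 − exp(−(k·t)^n)) is available as an optional
diagnostic of the sigmoid shape; the kinetic summary itself is
model-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "CrystallizationSeries",
    "KineticsSummary",
    "NormalizedSeries",
    "normalize_series",
    "kinetic_times",
    "AvramiModel",
    "AvramiResults",
    "NoDecayError",
]


class NoDecayError(RuntimeError):
    """The permittivity series shows no crystallization decay."""


@dataclass(frozen=True)
class CrystallizationSeries:
    """Time-indexed static permittivity during isothermal storage."""

    time: np.ndarray  # s, strictly increasing from 0
    eps_static: np.ndarray
    temperature: float  # K
    sample_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.eps_static, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("time and eps_static must be equal-length 1-D arrays")
        if t.size < 10:
            raise ValueError(f"series too short ({t.size} points, need >= 10)")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time must start at 0 and be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "eps_static", e)


@dataclass(frozen=True)
class NormalizedSeries:
    """Normalized conversion curve ε′_N(t) with the endpoints used."""

    time: np.ndarray
    eps_norm: np.ndarray
    eps_initial: float
    eps_final: float
    out_of_range: int = 0  # points outside [-0.05, 1.05]


@dataclass(frozen=True)
class KineticsSummary:
    """Threshold times of an isothermal crystallization run (seconds)."""

    onset_time: float | None
    half_life: float | None
    endset_time: float | None
    eps_initial: float
    eps_final: float

    def __post_init__(self) -> None:
        stamps = [
            s
            for s in (self.onset_time, self.half_life, self.endset_time)
            if s is not None
        ]
        if any(b < a for a, b in zip(stamps, stamps[1:])):
            raise ValueError("threshold times must be ordered onset <= t0.5 <= endset")

    @property
    def complete(self) -> bool:
        return None not in (self.onset_time, self.half_life, self.endset_time)


def normalize_series(
    cs: CrystallizationSeries,
    eps0: float | None = None,
    epsinf: float | None = None,
    *,
    plateau_fraction: float = 0.05,
) -> NormalizedSeries:
    """Normalized real permittivity ε′_N(t) = (ε′(0) − ε′(t)) / (ε′(0) − ε′(∞)).

    ε′(0) and ε′(∞), unless supplied, are estimated as the means of the
    first and last ``plateau_fraction`` of points.  Raises
    :class:`NoDecayError` when the initial level does not exceed the final
    one.  Values escaping [−0.05, 1.05] are counted in ``out_of_range``.
    """
    e = cs.eps_static
    n_win = max(1, int(round(plateau_fraction * e.size)))
    if eps0 is None:
        eps0 = float(e[:n_win].mean())
    if epsinf is None:
        epsinf = float(e[-n_win:].mean())
    if not eps0 > epsinf:
        raise NoDecayError(
            f"initial permittivity ({eps0:.4f}) does not exceed final "
            f"({epsinf:.4f}); no crystallization decay"
        )
    en = (eps0 - e) / (eps0 - epsinf)
    out = int(np.sum((en < -0.05) | (en > 1.05)))
    if out:
        warnings.warn(
            f"{out} normalized points outside [-0.05, 1.05]", stacklevel=2
        )
    return NormalizedSeries(
        time=cs.time, eps_norm=en, eps_initial=eps0, eps_final=epsinf, out_of_range=out
    )


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Time of first upward crossing of ``level``, linearly interpolated."""
    if y[0] >= level:
        return float(t[0])
    above = np.flatnonzero(y >= level)
    if above.size == 0:
        return None
    k = above[0]
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t[k])
    frac = (level - y0) / (y1 - y0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def kinetic_times(
    ns: NormalizedSeries,
    *,
    onset_level: float = 0.05,
    half_level: float = 0.5,
    endset_level: float = 0.95,
) -> KineticsSummary:
    """Onset, half-life and endset from threshold crossings of ε′_N(t).

    Thresholds default to 0.05 / 0.5 / 0.95.  A threshold the curve never
    reaches yields a None field (partial summary) with a warning.
    """
    t, y = ns.time, ns.eps_norm
    times = {}
    for name, level in [
        ("onset", onset_level),
        ("half", half_level),
        ("endset", endset_level),
    ]:
        times[name] = _first_crossing(t, y, level)
        if times[name] is None:
            warnings.warn(
                f"normalized series never reaches the {name} level {level}",
                stacklevel=2,
            )
    return KineticsSummary(
        onset_time=times["onset"],
        half_life=times["half"],
        endset_time=times["endset"],
        eps_initial=ns.eps_initial,
        eps_final=ns.eps_final,
    )


class AvramiModel:
    """Optional diagnostic fit ε′_N(t) = 1 − exp(−(k·t)^n)."""

    def __init__(self, normalized: NormalizedSeries):
        self.normalized = normalized

    def fit(self) -> "AvramiResults":
        t, y = self.normalized.time, self.normalized.eps_norm
        mask = (y > 1e-6) & (y < 1 - 1e-6) & (t > 0)
        if mask.sum() < 3:
            raise RuntimeError("too few points in the transition region")
        # linearized seed: ln(-ln(1-y)) = n ln k + n ln t
        lin_y = np.log(-np.log(1.0 - y[mask]))
        lin_t = np.log(t[mask])
        n0, c0 = np.polyfit(lin_t, lin_y, 1)
        k0 = np.exp(c0 / n0)

        def resid(v):
            k, n = v
            return 1.0 - np.exp(-((k * t[mask]) ** n)) - y[mask]

        sol = optimize.least_squares(
            resid, [k0, n0], bounds=([1e-12, 0.1], [np.inf, 10.0])
        )
        k, n = sol.x
        return AvramiResults(
            rate=float(k), exponent=float(n), residual_norm=float(np.linalg.norm(sol.fun))
        )


@dataclass(frozen=True)
class AvramiResults:
    rate: float  # k in 1/s
    exponent: float  # Avrami n

    residual_norm: float = float("nan")

    @property
    def half_life(self) -> float:
        """t0.5 = (ln 2)^(1/n) / k."""
        return np.log(2.0) ** (1.0 / self.exponent) / self.rate
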