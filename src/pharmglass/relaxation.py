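"""Relaxation-map analysis: VFT fits, Stickel derivative analysis, and the
derived dynamic quantities of a glass former.

The temperature dependence of the structural relaxation time τ_α in the
supercooled-liquid range is parameterized by the Vogel–Fulcher–Tammann
(VFT) law in the natural-log convention

    τ_α(T) = τ∞ · exp( B / (T − T0) )

with τ∞ reported as log10(τ∞/s), B in K (B = D·T0, D the strength
parameter) and T0 the Vogel temperature.  From fitted VFT parameters the
package derives:

* the kinetic glass transition Tg = T(τ_α = 100 s),
* isochronal temperatures T(τ_α = τ_target), e.g. τ_target = 0.63 μs,
* the fragility (steepness index) m = B·Tg / (ln10 · (Tg − T0)²).

Whether a single VFT covers the whole range is decided with the Stickel
derivative operator φ(T) = [−d log10 τ_α / dT]^(−1/2), which is linear in
T for exact VFT behaviour, φ = (T − T0)·(ln10/B)^(1/2); a slope break in
φ(T) marks a dynamic crossover between two VFT regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "RelaxationMap",
    "VFTParameters",
    "VFTModel",
    "VFTResults",
    "StickelResult",
    "stickel_transform",
    "detect_crossover",
    "second_regime_parameters",
    "vft_tau",
    "kinetic_tg",
    "isochronal_temperature",
    "fragility",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class RelaxationMap:
    """(T, τ_α) points for one sample, sorted by temperature."""

    temperature: np.ndarray  # K
    tau_alpha: np.ndarray  # s
    sample_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        tau = np.asarray(self.tau_alpha, dtype=float)
        if t.shape != tau.shape or t.ndim != 1:
            raise ValueError("temperature and tau_alpha must be equal-length 1-D")
        if np.unique(t).size != t.size:
            raise ValueError("temperatures must be distinct")
        if np.any(tau <= 0):
            raise ValueError("relaxation times must be positive")
        order = np.argsort(t)
        object.__setattr__(self, "temperature", t[order])
        object.__setattr__(self, "tau_alpha", tau[order])

    def __len__(self) -> int:
        return self.temperature.size


@dataclass(frozen=True)
class VFTParameters:
    """VFT parameters in the τ = τ∞·exp(B/(T−T0)) convention."""

    log10_tau_inf: float  # log10 of τ∞ in s
    B: float  # K
    T0_vogel: float  # K
    valid_range: tuple[float, float] | None = None  # (Tmin, Tmax) K

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError(f"B must be > 0, got {self.B}")
        if self.T0_vogel < 0:
            raise ValueError(f"T0 must be >= 0, got {self.T0_vogel}")
        if self.valid_range is not None and self.T0_vogel >= self.valid_range[0]:
            raise ValueError("Vogel T0 must lie below the valid temperature range")

    @property
    def tau_inf(self) -> float:
        return 10.0 ** self.log10_tau_inf

    @property
    def strength(self) -> float:
        """Strength parameter D = B / T0."""
        return self.B / self.T0_vogel


def vft_tau(temperature, p: VFTParameters):
    """τ_α(T) from the VFT law (natural-log convention)."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= p.T0_vogel):
        raise ValueError("temperature must exceed the Vogel temperature")
    out = p.tau_inf * np.exp(p.B / (t - p.T0_vogel))
    return float(out) if np.isscalar(temperature) else out


def kinetic_tg(p: VFTParameters, tau_ref: float = 100.0) -> float:
    """Kinetic glass transition T(τ_α = tau_ref), default τ_ref = 100 s.

    Closed-form VFT inversion: T = T0 + B / ln(τ_ref/τ∞).
    """
    if not tau_ref > p.tau_inf:
        raise ValueError("tau_ref must exceed the pre-exponential tau_inf")
    return p.T0_vogel + p.B / np.log(tau_ref / p.tau_inf)


def isochronal_temperature(p: VFTParameters, tau_target: float = 0.63e-6) -> float:
    """Temperature at which τ_α equals ``tau_target`` (default 0.63 μs)."""
    return kinetic_tg(p, tau_ref=tau_target)


def fragility(p: VFTParameters, tg: float | None = None) -> float:
    """Steepness index m = B·Tg / (ln10 · (Tg − T0)²) at Tg = T(τ=100 s)."""
    if tg is None:
        tg = kinetic_tg(p)
    if not tg > p.T0_vogel:
        raise ValueError("Tg must exceed the Vogel temperature")
    return p.B * tg / (LN10 * (tg - p.T0_vogel) ** 2)


def second_regime_parameters(
    vft1: VFTParameters, t_cross: float, b2: float
) -> VFTParameters:
    """High-temperature VFT regime joining ``vft1`` at ``t_cross``.

    The two regimes of a dynamic crossover share the value of τ_α and of
    the Stickel operator φ at T_cross (the two lines intersect there).
    Given the new activation parameter ``b2`` this fixes the other two:

        T0' = T_cross − (b2/B1)^(1/2) · (T_cross − T0)
        log10 τ∞' = log10 τ_α(T_cross) − b2 / (ln10 · (T_cross − T0'))
    """
    if t_cross <= vft1.T0_vogel:
        raise ValueError("t_cross must exceed the Vogel temperature of vft1")
    t0_2 = t_cross - np.sqrt(b2 / vft1.B) * (t_cross - vft1.T0_vogel)
    log_tau_at_cross = vft1.log10_tau_inf + vft1.B / (LN10 * (t_cross - vft1.T0_vogel))
    log_tau_inf2 = log_tau_at_cross - b2 / (LN10 * (t_cross - t0_2))
    return VFTParameters(log10_tau_inf=float(log_tau_inf2), B=float(b2), T0_vogel=float(t0_2))


class VFTModel:
    """Weighted least-squares VFT fit of a relaxation map.

    The objective is log10 τ_α = log10 τ∞ + B/(ln10·(T − T0)), fitted with
    bound constraints B > 0 and 0 ≤ T0 < min(T).  The initial guess comes
    from the Stickel linearization (φ is linear in T with intercept −T0·slope),
    which is exact for VFT data.
    """

    def __init__(
        self,
        relaxation_map: RelaxationMap,
        fit_range: tuple[float, float] | None = None,
    ):
        self.map = relaxation_map
        self.fit_range = fit_range
        t, tau = relaxation_map.temperature, relaxation_map.tau_alpha
        if fit_range is not None:
            mask = (t >= fit_range[0]) & (t <= fit_range[1])
            t, tau = t[mask], tau[mask]
        if t.size < 5:
            raise ValueError("need at least 5 points in the fit range")
        self._t = t
        self._logtau = np.log10(tau)

    def _initial(self) -> tuple[float, float, float]:
        t, y = self._t, self._logtau
        # Stickel-space seed: phi = (T - T0) sqrt(ln10/B)
        dy = np.gradient(y, t)
        usable = dy < 0
        if usable.sum() >= 3:
            phi = (-dy[usable]) ** -0.5
            slope, intercept = np.polyfit(t[usable], phi, 1)
            if slope > 0:
                t0 = max(-intercept / slope, 0.0)
                b = LN10 / slope**2
                if t0 < t.min():
                    logtinf = float(np.mean(y - b / (LN10 * (t - t0))))
                    return logtinf, b, t0
        # fallback: generic supercooled-liquid guess
        t0 = max(0.5 * t.min(), t.min() - 100.0)
        return -12.0, 1500.0, t0

    def fit(self, weights: np.ndarray | None = None) -> "VFTResults":
        t, y = self._t, self._logtau
        if weights is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(weights, dtype=float)
        li, bi, t0i = self._initial()
        params = Parameters()
        params.add("log10_tau_inf", value=li, min=-20.0, max=0.0)
        params.add("B", value=bi, min=1e-6)
        params.add("T0", value=min(t0i, t.min() - 2.0), min=0.0, max=t.min() - 1e-6)

        def resid(p: Parameters) -> np.ndarray:
            v = p.valuesdict()
            model = v["log10_tau_inf"] + v["B"] / (LN10 * (t - v["T0"]))
            return w * (model - y)

        out = minimize(resid, params, method="least_squares")
        if not out.success:
            raise RuntimeError("VFT fit did not converge")
        v = out.params.valuesdict()
        if v["T0"] >= t.min():
            raise RuntimeError("fitted Vogel temperature not below the data range")
        fitted = VFTParameters(
            log10_tau_inf=float(v["log10_tau_inf"]),
            B=float(v["B"]),
            T0_vogel=float(v["T0"]),
            valid_range=(float(t.min()), float(t.max())),
        )
        stderr = {
            name: (
                float(out.params[key].stderr)
                if out.params[key].stderr is not None
                else None
            )
            for name, key in [
                ("log10_tau_inf", "log10_tau_inf"),
                ("B", "B"),
                ("T0_vogel", "T0"),
            ]
        }
        return VFTResults(
            model=self,
            params=fitted,
            stderr=stderr,
            residual_norm=float(np.linalg.norm(out.residual)),
            nfev=int(out.nfev),
        )


@dataclass(frozen=True)
class VFTResults:
    """Fitted VFT parameters with derived dynamic quantities."""

    model: VFTModel | None
    params: VFTParameters
    stderr: dict
    residual_norm: float
    nfev: int = 0

    @classmethod
    def from_parameters(cls, p: VFTParameters) -> "VFTResults":
        """Wrap externally supplied (e.g. literature) VFT parameters."""
        return cls(model=None, params=p, stderr={}, residual_norm=float("nan"))

    def tau(self, temperature):
        return vft_tau(temperature, self.params)

    def temperature_at_tau(self, tau_target: float) -> float:
        return kinetic_tg(self.params, tau_ref=tau_target)

    def kinetic_tg(self, tau_ref: float = 100.0) -> float:
        return kinetic_tg(self.params, tau_ref=tau_ref)

    def isochronal_temperature(self, tau_target: float = 0.63e-6) -> float:
        return isochronal_temperature(self.params, tau_target=tau_target)

    def fragility(self, tg: float | None = None) -> float:
        return fragility(self.params, tg=tg)

    def summary(self) -> str:
        p = self.params
        se = self.stderr

        def fmt(name: str, value: float, unit: str = "") -> str:
            s = se.get(name)
            err = f" +/- {s:.3g}" if s is not None else ""
            return f"{name:15s} {value:12.4f}{err} {unit}"

        lines = [
            "VFT fit (tau = tau_inf * exp(B/(T-T0)))",
            "=" * 48,
            fmt("log10_tau_inf", p.log10_tau_inf, "log10(s)"),
            fmt("B", p.B, "K"),
            fmt("T0_vogel", p.T0_vogel, "K"),
            f"{'Tg (tau=100 s)':15s} {self.kinetic_tg():12.1f} K",
            f"{'m_p':15s} {self.fragility():12.1f}",
            f"{'T(0.63 us)':15s} {self.isochronal_temperature():12.1f} K",
        ]
        if p.valid_range is not None:
            lines.append(
                f"{'valid range':15s} {p.valid_range[0]:.1f} - {p.valid_range[1]:.1f} K"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class StickelResult:
    """Stickel derivative transform and optional two-segment description."""

    temperature: np.ndarray  # K, points where φ is defined
    phi: np.ndarray  # [−d log10 τ / dT]^(−1/2)
    segments: tuple[tuple[float, float, tuple[float, float]], ...] = ()
    # each segment: (slope, intercept, (Tmin, Tmax))
    t_cross: float | None = None


def stickel_transform(relaxation_map: RelaxationMap) -> StickelResult:
    """Derivative linearization φ(T) = [−d log10 τ_α/dT]^(−1/2).

    The derivative is taken by central differences on neighbouring raw
    points (no smoothing).  Points with non-negative derivative (physically
    impossible for relaxation slowing on cooling) are dropped with a
    warning; fewer than 3 usable points is an error.
    """
    t = relaxation_map.temperature
    y = np.log10(relaxation_map.tau_alpha)
    if t.size < 4:
        raise ValueError("need at least 4 points for the Stickel transform")
    ti = t[1:-1]
    deriv = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    usable = deriv < 0
    if not np.all(usable):
        warnings.warn(
            f"dropped {int((~usable).sum())} Stickel points with non-negative "
            "d log10(tau)/dT",
            stacklevel=2,
        )
    ti, deriv = ti[usable], deriv[usable]
    if ti.size < 3:
        raise ValueError("fewer than 3 usable Stickel points")
    phi = (-deriv) ** -0.5
    return StickelResult(temperature=ti, phi=phi)


def _line_ssr(t: np.ndarray, phi: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, SSR)."""
    slope, intercept = np.polyfit(t, phi, 1)
    ssr = float(np.sum((phi - (slope * t + intercept)) ** 2))
    return float(slope), float(intercept), ssr


def detect_crossover(
    sr: StickelResult,
    *,
    f_threshold: float = 4.0,
    min_segment: int = 3,
    collinear_rtol: float = 1e-8,
    slope_rtol: float = 0.02,
) -> StickelResult:
    """Two-segment piecewise-linear description of the Stickel transform.

    Every admissible breakpoint (≥ ``min_segment`` points per side) is
    tried; the best two-line fit is accepted only when (i) it improves on
    the single-line fit by an F-ratio above ``f_threshold`` and (ii) the
    two slopes differ by more than ``slope_rtol`` relative — a genuine
    VFT1/VFT2 crossover changes the Stickel slope by the factor
    (B1/B2)^(1/2), whereas the residual curvature of finite-difference
    derivatives of exact VFT data perturbs the slopes by well under 1%.
    The crossover temperature is the intersection of the two fitted lines.
    Exactly (or numerically) collinear transforms — single-line residual
    below ``collinear_rtol`` of the total variance — report no crossover.

    Returns a new :class:`StickelResult` carrying segments and ``t_cross``
    (None for single-VFT behaviour).
    """
    t, phi = sr.temperature, sr.phi
    n = t.size
    if n < 2 * min_segment:
        return StickelResult(temperature=t, phi=phi, segments=(), t_cross=None)

    slope1, inter1, ssr_single = _line_ssr(t, phi)
    ss_total = float(np.sum((phi - phi.mean()) ** 2))
    if ss_total <= 0 or ssr_single <= collinear_rtol * ss_total:
        seg = ((slope1, inter1, (float(t[0]), float(t[-1]))),)
        return StickelResult(temperature=t, phi=phi, segments=seg, t_cross=None)

    best = None
    for k in range(min_segment, n - min_segment + 1):
        s_lo, i_lo, ssr_lo = _line_ssr(t[:k], phi[:k])
        s_hi, i_hi, ssr_hi = _line_ssr(t[k:], phi[k:])
        ssr = ssr_lo + ssr_hi
        if best is None or ssr < best[0]:
            best = (ssr, k, (s_lo, i_lo), (s_hi, i_hi))
    assert best is not None
    ssr_two, k, (s_lo, i_lo), (s_hi, i_hi) = best

    dof_two = max(n - 4, 1)
    f_ratio = ((ssr_single - ssr_two) / 2.0) / max(ssr_two / dof_two, 1e-300)
    slope_sep = abs(s_hi - s_lo) / max(abs(s_lo), abs(s_hi), 1e-300)
    if f_ratio <= f_threshold or slope_sep <= slope_rtol:
        seg = ((slope1, inter1, (float(t[0]), float(t[-1]))),)
        return StickelResult(temperature=t, phi=phi, segments=seg, t_cross=None)

    t_cross = (i_hi - i_lo) / (s_lo - s_hi)
    segments = (
        (s_lo, i_lo, (float(t[0]), float(t[k - 1]))),
        (s_hi, i_hi, (float(t[k]), float(t[-1]))),
    )
    return StickelResult(
        temperature=t, phi=phi, segments=segments, t_cross=float(t_cross)
    )
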