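"""Havriliak–Negami modelling of broadband dielectric spectra.

The complex permittivity of a supercooled liquid near the structural (α)
relaxation is described by the Havriliak–Negami (HN) function with a
dc-conductivity term:

    ε*(ω) = ε∞ + Δε / (1 + (iωτ_HN)^a)^b  −  i σ_dc / (ε0 ω)

where ε∞ is the high-frequency limit permittivity, Δε the dielectric
strength, τ_HN the HN relaxation time, a and b the symmetric and
asymmetric broadening exponents (0 < a ≤ 1, 0 < ab ≤ 1) and σ_dc the dc
conductivity.  Loss spectra are reported in the positive convention
ε″ = −Im ε*.

The structural relaxation time is taken at the loss-peak position, which
for the HN shape has the closed form

    τ_α = τ_HN · [sin(πa / (2 + 2b))]^(−1/a) · [sin(πab / (2 + 2b))]^(1/a)

:class:`HavriliakNegamiModel` wraps the least-squares fit of a measured
loss spectrum (lmfit under the hood) and returns an :class:`HNResults`
carrying estimates, uncertainties and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy.constants import epsilon_0

__all__ = [
    "DielectricSpectrum",
    "HNParameters",
    "hn_model",
    "tau_alpha_from_hn",
    "HavriliakNegamiModel",
    "HNResults",
]


@dataclass(frozen=True)
class DielectricSpectrum:
    """Frequency-indexed complex permittivity at one temperature."""

    frequency: np.ndarray  # Hz, strictly increasing
    eps_real: np.ndarray
    eps_imag: np.ndarray  # positive-loss convention
    temperature: float  # K

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        ei = np.asarray(self.eps_imag, dtype=float)
        if not (f.shape == er.shape == ei.shape) or f.ndim != 1:
            raise ValueError("frequency, eps_real, eps_imag must be equal-length 1-D")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequency must be positive and strictly increasing")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "eps_real", er)
        object.__setattr__(self, "eps_imag", ei)


@dataclass(frozen=True)
class HNParameters:
    """Havriliak–Negami shape and conductivity parameters."""

    eps_inf: float
    delta_eps: float
    tau_hn: float  # s
    a: float  # symmetric broadening, 0 < a <= 1
    b: float  # asymmetric broadening, 0 < a*b <= 1
    sigma_dc: float = 0.0  # S/m

    def __post_init__(self) -> None:
        if not self.delta_eps > 0:
            raise ValueError(f"delta_eps must be > 0, got {self.delta_eps}")
        if not self.tau_hn > 0:
            raise ValueError(f"tau_hn must be > 0, got {self.tau_hn}")
        if not 0 < self.a <= 1:
            raise ValueError(f"a must be in (0, 1], got {self.a}")
        if not 0 < self.a * self.b <= 1 + 1e-12:
            raise ValueError(f"a*b must be in (0, 1], got {self.a * self.b}")
        if self.sigma_dc < 0:
            raise ValueError(f"sigma_dc must be >= 0, got {self.sigma_dc}")


def hn_model(frequency, p: HNParameters) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the HN + conductivity model at the given frequencies (Hz).

    Returns ``(eps_real, eps_imag)`` with the loss in the positive
    convention.  The conductivity term contributes to the loss only.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    hn = p.delta_eps / (1.0 + (1j * omega * p.tau_hn) ** p.a) ** p.b
    eps_real = p.eps_inf + hn.real
    eps_imag = -hn.imag + p.sigma_dc / (epsilon_0 * omega)
    return eps_real, eps_imag


def tau_alpha_from_hn(p: HNParameters) -> float:
    """Structural relaxation time τ_α = 1/ω_max of the HN loss peak."""
    a, b = p.a, p.b
    return float(
        p.tau_hn
        * np.sin(np.pi * a / (2.0 + 2.0 * b)) ** (-1.0 / a)
        * np.sin(np.pi * a * b / (2.0 + 2.0 * b)) ** (1.0 / a)
    )


def _loss_peak_index(frequency: np.ndarray, loss: np.ndarray) -> int:
    """Index of the α-relaxation loss maximum, ignoring the dc upturn.

    The conductivity wing rises monotonically toward low frequency; the
    α peak is the most prominent interior local maximum.  Falls back to the
    global argmax when no interior peak exists.
    """
    from scipy.signal import find_peaks

    logy = np.log10(np.clip(loss, 1e-300, None))
    peaks, props = find_peaks(logy, prominence=0.05)
    if peaks.size:
        return int(peaks[np.argmax(props["prominences"])])
    return int(np.argmax(loss))


class HavriliakNegamiModel:
    """Least-squares HN + conductivity model for one loss spectrum.

    By default only ε″ enters the objective (loss-spectrum fitting); set
    ``fit_real=True`` to co-fit ε′.  Residuals are taken on log10 of the
    loss so that decades-spanning spectra are weighted uniformly, which for
    small deviations is equivalent to relative weighting.
    """

    def __init__(self, spectrum: DielectricSpectrum, *, fit_real: bool = False):
        self.spectrum = spectrum
        self.fit_real = fit_real

    # shape-guess grid for multi-start fitting: (a, a*b) candidates
    _SHAPE_SEEDS: tuple[tuple[float, float], ...] = (
        (0.8, 0.48),
        (1.0, 1.0),
        (0.9, 0.8),
        (0.6, 0.35),
    )

    def _peak_consistent_init(self, a: float, ab: float) -> HNParameters:
        """Initial parameters for a given shape guess, with Δε and τ_HN set
        so the model loss peak matches the observed one in position and
        height."""
        spec = self.spectrum
        i_pk = _loss_peak_index(spec.frequency, spec.eps_imag)
        f_pk = spec.frequency[i_pk]
        height = float(spec.eps_imag[i_pk])
        b = ab / a
        # unit-strength, unit-time HN loss maximum for this shape
        probe = HNParameters(eps_inf=0.0, delta_eps=1.0, tau_hn=1.0, a=a, b=b)
        omega = np.logspace(-4, 4, 801)
        _, unit_loss = hn_model(omega / (2.0 * np.pi), probe)
        h_unit = float(unit_loss.max())
        tau_alpha = 1.0 / (2.0 * np.pi * f_pk)
        tau_hn = tau_alpha / tau_alpha_from_hn(probe)
        # dc estimate: excess of the measured low-frequency loss over the
        # HN-wing contribution of this shape guess
        trial = HNParameters(
            eps_inf=0.0, delta_eps=height / h_unit, tau_hn=tau_hn, a=a, b=b
        )
        _, wing = hn_model(spec.frequency[:1], trial)
        excess = float(spec.eps_imag[0] - wing[0])
        sigma0 = max(excess, 0.0) * epsilon_0 * 2.0 * np.pi * float(spec.frequency[0])
        return HNParameters(
            eps_inf=float(max(spec.eps_real.min(), 1e-6)),
            delta_eps=height / h_unit,
            tau_hn=tau_hn,
            a=a,
            b=b,
            sigma_dc=sigma0,
        )

    @property
    def _omega_min(self) -> float:
        return 2.0 * np.pi * float(self.spectrum.frequency[0])

    def _initial_parameters(self, init: HNParameters) -> Parameters:
        params = Parameters()
        params.add("eps_inf", value=init.eps_inf, min=0.0)
        params.add("delta_eps", value=init.delta_eps, min=1e-12)
        params.add("log10_tau", value=np.log10(init.tau_hn), min=-15, max=6)
        params.add("a", value=init.a, min=1e-3, max=1.0)
        # enforce 0 < a*b <= 1 by fitting the product
        params.add("ab", value=min(init.a * init.b, 1.0), min=1e-3, max=1.0)
        # conductivity expressed as its loss contribution at the lowest
        # measured frequency — O(1), unlike sigma_dc itself (~1e-11 S/m)
        params.add(
            "cond_ref",
            value=init.sigma_dc / (epsilon_0 * self._omega_min),
            min=0.0,
        )
        return params

    def _unpack(self, params: Parameters) -> HNParameters:
        v = params.valuesdict()
        a = v["a"]
        return HNParameters(
            eps_inf=v["eps_inf"],
            delta_eps=v["delta_eps"],
            tau_hn=10.0 ** v["log10_tau"],
            a=a,
            b=v["ab"] / a,
            sigma_dc=v["cond_ref"] * epsilon_0 * self._omega_min,
        )

    def _residuals(self, params: Parameters) -> np.ndarray:
        p = self._unpack(params)
        er, ei = hn_model(self.spectrum.frequency, p)
        res = np.log10(np.clip(ei, 1e-300, None)) - np.log10(
            np.clip(self.spectrum.eps_imag, 1e-300, None)
        )
        if self.fit_real:
            res_r = np.log10(np.clip(er, 1e-300, None)) - np.log10(
                np.clip(self.spectrum.eps_real, 1e-300, None)
            )
            res = np.concatenate([res, res_r])
        return res

    def fit(self, init: HNParameters | None = None) -> "HNResults":
        """Fit the spectrum; returns an :class:`HNResults`.

        Without an explicit ``init`` the fit is multi-started from a small
        grid of shape guesses, each with peak-consistent strength and time
        seeds, and the lowest-residual solution is kept (the loss-only HN
        objective has shallow local minima along the a-Δε-τ valley).
        """
        spec = self.spectrum
        i_pk = _loss_peak_index(spec.frequency, spec.eps_imag)
        peak_at_boundary = i_pk in (0, spec.frequency.size - 1)
        if peak_at_boundary:
            warnings.warn(
                "loss peak lies at a frequency boundary; HN fit may be unreliable",
                stacklevel=2,
            )
        if init is not None:
            starts = [init]
        else:
            starts = [self._peak_consistent_init(a, ab) for a, ab in self._SHAPE_SEEDS]
        out = None
        for start in starts:
            candidate = minimize(
                self._residuals, self._initial_parameters(start), method="leastsq"
            )
            if out is None or np.linalg.norm(candidate.residual) < np.linalg.norm(
                out.residual
            ):
                out = candidate
        assert out is not None
        fitted = self._unpack(out.params)
        stderr: dict[str, float | None] = {}
        for name in ("eps_inf", "delta_eps", "log10_tau", "a", "ab", "cond_ref"):
            par = out.params[name]
            stderr[name] = float(par.stderr) if par.stderr is not None else None
        return HNResults(
            model=self,
            params=fitted,
            stderr=stderr,
            residual_norm=float(np.linalg.norm(out.residual)),
            success=bool(out.success),
            peak_at_boundary=peak_at_boundary,
            nfev=int(out.nfev),
        )


@dataclass(frozen=True)
class HNResults:
    """Fitted HN parameters with diagnostics."""

    model: HavriliakNegamiModel
    params: HNParameters
    stderr: dict
    residual_norm: float
    success: bool
    peak_at_boundary: bool
    nfev: int

    @property
    def tau_alpha(self) -> float:
        """Loss-peak structural relaxation time in seconds."""
        return tau_alpha_from_hn(self.params)

    def predict(self, frequency=None) -> tuple[np.ndarray, np.ndarray]:
        if frequency is None:
            frequency = self.model.spectrum.frequency
        return hn_model(frequency, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Havriliak-Negami fit",
            "=" * 40,
            f"T               {self.model.spectrum.temperature:10.2f} K",
            f"eps_inf         {p.eps_inf:10.4f}",
            f"delta_eps       {p.delta_eps:10.4f}",
            f"tau_HN          {p.tau_hn:10.4e} s",
            f"a               {p.a:10.4f}",
            f"b               {p.b:10.4f}",
            f"sigma_dc        {p.sigma_dc:10.4e} S/m",
            f"tau_alpha       {self.tau_alpha:10.4e} s",
            f"residual norm   {self.residual_norm:10.4e}",
            f"converged       {self.success}",
        ]
        if self.peak_at_boundary:
            lines.append("WARNING: loss peak at frequency boundary")
        return "\n".join(lines)
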