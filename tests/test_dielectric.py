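"""Havriliak–Negami model evaluation, fitting and the loss-peak time
conversion, checked against polar-form and numeric-argmax oracles."""

import warnings

import numpy as np
import pytest

from pharmglass.dielectric import (
    DielectricSpectrum,
    HavriliakNegamiModel,
    HNParameters,
    hn_model,
    tau_alpha_from_hn,
)

FREQ = np.logspace(-1, 7, 81)


def _spectrum(p: HNParameters, freq=FREQ, temperature=300.0) -> DielectricSpectrum:
    er, ei = hn_model(freq, p)
    return DielectricSpectrum(freq, er, ei, temperature)


# --- model evaluation -------------------------------------------------------

def test_debye_limit_peak_at_reciprocal_tau():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=1.0, b=1.0)
    f = np.logspace(0, 7, 100_001)
    _, loss = hn_model(f, p)
    f_pk = f[np.argmax(loss)]
    assert 2 * np.pi * f_pk * p.tau_hn == pytest.approx(1.0, rel=1e-3)
    # Debye loss maximum is delta_eps / 2
    assert loss.max() == pytest.approx(4.0, rel=1e-4)


def test_high_frequency_limit_is_eps_inf():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=0.8, b=0.6)
    er, _ = hn_model(np.array([1e15]), p)
    assert er[0] == pytest.approx(3.0, abs=1e-3)


def test_polar_form_oracle():
    # independent evaluation via polar decomposition of 1 + (i*w*tau)^a
    p = HNParameters(eps_inf=2.5, delta_eps=6.0, tau_hn=3e-5, a=0.73, b=0.45,
                     sigma_dc=2e-12)
    omega = 2 * np.pi * FREQ
    wt = (omega * p.tau_hn) ** p.a
    re = 1.0 + wt * np.cos(np.pi * p.a / 2.0)
    im = wt * np.sin(np.pi * p.a / 2.0)
    r = np.hypot(re, im) ** p.b
    theta = p.b * np.arctan2(im, re)
    eps_r_oracle = p.eps_inf + p.delta_eps * np.cos(theta) / r
    from scipy.constants import epsilon_0

    eps_i_oracle = p.delta_eps * np.sin(theta) / r + p.sigma_dc / (epsilon_0 * omega)
    er, ei = hn_model(FREQ, p)
    assert np.allclose(er, eps_r_oracle, rtol=1e-12)
    assert np.allclose(ei, eps_i_oracle, rtol=1e-9)


def test_conductivity_only_affects_loss():
    base = HNParameters(3.0, 8.0, 1e-4, 0.8, 0.6, sigma_dc=0.0)
    cond = HNParameters(3.0, 8.0, 1e-4, 0.8, 0.6, sigma_dc=1e-10)
    er0, ei0 = hn_model(FREQ, base)
    er1, ei1 = hn_model(FREQ, cond)
    assert np.array_equal(er0, er1)
    assert np.all(ei1 >= ei0)


def test_parameter_invariants_enforced():
    for bad in [
        dict(delta_eps=-1.0),
        dict(tau_hn=0.0),
        dict(a=1.2),
        dict(b=2.0),  # a*b = 1.6 > 1
        dict(sigma_dc=-1e-12),
    ]:
        kwargs = dict(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=0.8, b=0.6)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            HNParameters(**kwargs)


# --- tau_alpha conversion ---------------------------------------------------

def test_debye_tau_alpha_equals_tau_hn():
    p = HNParameters(3.0, 8.0, 1e-4, 1.0, 1.0)
    assert tau_alpha_from_hn(p) == pytest.approx(1e-4, rel=1e-12)


@pytest.mark.parametrize("a,b", [(0.8, 0.6), (0.6, 0.9), (0.95, 0.3), (0.5, 1.5)])
def test_tau_alpha_matches_numeric_argmax(a, b):
    p = HNParameters(3.0, 8.0, 1e-4, a, b)
    f = np.logspace(-2, 8, 1_000_000)
    _, loss = hn_model(f, p)
    tau_numeric = 1.0 / (2 * np.pi * f[np.argmax(loss)])
    assert tau_alpha_from_hn(p) == pytest.approx(tau_numeric, rel=1e-3)


def test_tau_alpha_shift_direction_with_b():
    # decreasing b moves the loss peak to higher frequency (smaller tau)
    taus = [
        tau_alpha_from_hn(HNParameters(3.0, 8.0, 1e-4, 0.8, b)) for b in (0.9, 0.6, 0.3)
    ]
    assert taus[0] > taus[1] > taus[2]


# --- fitting ----------------------------------------------------------------

def test_noiseless_fit_recovers_parameters():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=0.8, b=0.6,
                     sigma_dc=1e-11)
    res = HavriliakNegamiModel(_spectrum(p)).fit()
    q = res.params
    assert q.delta_eps == pytest.approx(p.delta_eps, rel=1e-3)
    assert q.tau_hn == pytest.approx(p.tau_hn, rel=1e-3)
    assert q.a == pytest.approx(p.a, rel=1e-3)
    assert q.b == pytest.approx(p.b, rel=1e-3)
    assert q.sigma_dc == pytest.approx(p.sigma_dc, rel=1e-3)
    assert res.tau_alpha == pytest.approx(tau_alpha_from_hn(p), rel=1e-3)


def test_noiseless_cofit_recovers_eps_inf():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=0.8, b=0.6)
    res = HavriliakNegamiModel(_spectrum(p), fit_real=True).fit()
    assert res.params.eps_inf == pytest.approx(3.0, rel=1e-3)


def test_monte_carlo_tau_recovery_under_noise():
    # 1% multiplicative loss noise: median |delta log10 tau_HN| < 0.02
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=0.8, b=0.6)
    er, ei = hn_model(FREQ, p)
    errors = []
    rng = np.random.default_rng(2024)
    for _ in range(50):
        noisy = ei * (1.0 + rng.normal(0.0, 0.01, ei.shape))
        spec = DielectricSpectrum(FREQ, er, np.abs(noisy), 300.0)
        res = HavriliakNegamiModel(spec).fit()
        errors.append(abs(np.log10(res.params.tau_hn) - np.log10(p.tau_hn)))
    assert np.median(errors) < 0.02


def test_debye_data_fitted_with_free_shape():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=1.0, b=1.0)
    res = HavriliakNegamiModel(_spectrum(p)).fit()
    assert res.params.a * res.params.b == pytest.approx(1.0, abs=0.02)


def test_boundary_peak_warns():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=10.0, a=1.0, b=1.0)
    spec = _spectrum(p)  # peak far below 0.1 Hz
    with pytest.warns(UserWarning, match="boundary"):
        HavriliakNegamiModel(spec).fit()


def test_fit_invariant_to_frequency_rescaling():
    p = HNParameters(eps_inf=3.0, delta_eps=8.0, tau_hn=1e-4, a=0.8, b=0.6)
    res1 = HavriliakNegamiModel(_spectrum(p)).fit()
    scale = 1e3
    p_scaled = HNParameters(3.0, 8.0, 1e-4 / scale, 0.8, 0.6)
    res2 = HavriliakNegamiModel(_spectrum(p_scaled, freq=FREQ * scale)).fit()
    assert res2.params.tau_hn * scale == pytest.approx(res1.params.tau_hn, rel=1e-6)
    assert res2.params.a == pytest.approx(res1.params.a, rel=1e-6)


def test_summary_mentions_key_parameters():
    p = HNParameters(3.0, 8.0, 1e-4, 0.8, 0.6)
    text = HavriliakNegamiModel(_spectrum(p)).fit().summary()
    for token in ("tau_HN", "delta_eps", "tau_alpha"):
        assert token in text
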