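"""VFT fitting and inversion, Stickel analysis, crossover detection, and
the derived dynamic quantities checked against the published parameter
registry."""

import numpy as np
import pytest

from pharmglass.presets import VFT_PRESETS
from pharmglass.relaxation import (
    RelaxationMap,
    VFTModel,
    VFTParameters,
    VFTResults,
    detect_crossover,
    fragility,
    isochronal_temperature,
    kinetic_tg,
    second_regime_parameters,
    stickel_transform,
    vft_tau,
)


def _map_from(p: VFTParameters, n=9, span=(10.0, 60.0), label="") -> RelaxationMap:
    tg = kinetic_tg(p)
    temps = np.linspace(tg + span[0], tg + span[1], n)
    return RelaxationMap(temps, vft_tau(temps, p), sample_label=label)


# --- closed-form inversions -------------------------------------------------

@pytest.mark.parametrize(
    "label, expected_tg",
    [("SVT", 303), ("70/10/20", 311), ("10/20/70", 263)],
)
def test_kinetic_tg_reproduces_reported_values(label, expected_tg):
    assert round(kinetic_tg(VFT_PRESETS[label].vft)) == expected_tg


@pytest.mark.parametrize(
    "label, expected_m",
    [("SVT", 91), ("FEN", 95), ("70/10/20", 102)],
)
def test_fragility_reproduces_reported_values(label, expected_m):
    assert round(fragility(VFT_PRESETS[label].vft)) == expected_m


@pytest.mark.parametrize(
    "label, expected_t",
    [("SVT", 353), ("70/10/20", 369), ("10/20/70", 315), ("5.3/10.5/84.2", 307)],
)
def test_isochronal_temperature_reproduces_reported_values(label, expected_t):
    assert round(isochronal_temperature(VFT_PRESETS[label].vft)) == expected_t


def test_inversion_is_exact_round_trip():
    p = VFT_PRESETS["SVT"].vft
    for tau_ref in (100.0, 0.63e-6, 1e-9):
        t = kinetic_tg(p, tau_ref=tau_ref)
        assert vft_tau(t, p) == pytest.approx(tau_ref, rel=1e-12)


def test_isochronal_at_100s_equals_kinetic_tg():
    p = VFT_PRESETS["FEN"].vft
    assert isochronal_temperature(p, tau_target=100.0) == kinetic_tg(p)


def test_tau_ref_scale_identity():
    # tau_ref = tau_inf * e^B gives T = T0 + 1 (small B so e^B is finite)
    p = VFTParameters(-12.0, 50.0, 220.0)
    assert kinetic_tg(p, tau_ref=p.tau_inf * np.exp(p.B)) == pytest.approx(
        p.T0_vogel + 1.0
    )


def test_arrhenius_limit_fragility():
    p = VFTParameters(-12.0, 5000.0, 1e-9)
    tg = kinetic_tg(p)
    assert fragility(p) == pytest.approx(p.B / (np.log(10.0) * tg), rel=1e-6)


def test_domain_errors():
    p = VFTParameters(-12.0, 1500.0, 220.0)
    with pytest.raises(ValueError):
        kinetic_tg(p, tau_ref=1e-13)  # below tau_inf
    with pytest.raises(ValueError):
        fragility(p, tg=200.0)  # below Vogel temperature


# --- VFT fitting ------------------------------------------------------------

def test_noiseless_fit_recovers_parameters_4_sig_figs():
    p_true = VFT_PRESETS["10/20/70"].vft
    res = VFTModel(_map_from(p_true)).fit()
    assert res.params.B == pytest.approx(p_true.B, rel=5e-4)
    assert res.params.T0_vogel == pytest.approx(p_true.T0_vogel, rel=5e-4)
    assert res.params.log10_tau_inf == pytest.approx(p_true.log10_tau_inf, abs=5e-3)


def test_arrhenius_data_fitted_with_bounded_t0():
    temps = np.linspace(300.0, 400.0, 12)
    tau = 1e-12 * np.exp(3000.0 / temps)  # T0 = 0 limit
    res = VFTModel(RelaxationMap(temps, tau)).fit()
    assert res.params.T0_vogel < 5.0


def test_fit_under_noise_recovers_b_within_5_percent():
    p_true = VFT_PRESETS["SVT"].vft
    rmap = _map_from(p_true, n=15)
    rng = np.random.default_rng(7)
    rel_errors = []
    for _ in range(100):
        noisy = rmap.tau_alpha * 10 ** rng.normal(0.0, 0.02, rmap.tau_alpha.shape)
        try:
            res = VFTModel(RelaxationMap(rmap.temperature, noisy)).fit()
        except ValueError:
            continue  # noise broke monotonicity; skip draw
        rel_errors.append(abs(res.params.B - p_true.B) / p_true.B)
    assert np.median(rel_errors) < 0.05


def test_fit_range_restriction():
    p = VFT_PRESETS["SVT"].vft
    rmap = _map_from(p, n=15)
    lo, hi = rmap.temperature[3], rmap.temperature[12]
    res = VFTModel(rmap, fit_range=(lo, hi)).fit()
    assert res.params.valid_range == (lo, hi)


def test_results_summary_contains_derived_rows():
    res = VFTResults.from_parameters(VFT_PRESETS["SVT"].vft)
    text = res.summary()
    assert "Tg" in text and "m_p" in text and "0.63" in text


# --- Stickel analysis -------------------------------------------------------

def test_stickel_transform_of_exact_vft_is_linear():
    p = VFT_PRESETS["SVT"].vft
    sr = stickel_transform(_map_from(p, n=15))
    r2 = np.corrcoef(sr.temperature, sr.phi)[0, 1] ** 2
    assert r2 > 0.9999
    # slope consistent with (ln10 / B)^(1/2)
    slope = np.polyfit(sr.temperature, sr.phi, 1)[0]
    assert slope == pytest.approx(np.sqrt(np.log(10.0) / p.B), rel=1e-3)


def test_single_vft_reports_no_crossover():
    p = VFT_PRESETS["10/20/70"].vft
    sr = detect_crossover(stickel_transform(_map_from(p, n=15)))
    assert sr.t_cross is None
    assert len(sr.segments) == 1


def test_exactly_collinear_transform_reports_no_crossover():
    from pharmglass.relaxation import StickelResult

    t = np.linspace(300.0, 400.0, 12)
    sr = detect_crossover(StickelResult(temperature=t, phi=0.03 * (t - 220.0)))
    assert sr.t_cross is None


def test_two_regime_crossover_recovered():
    p1 = VFT_PRESETS["SVT"].vft
    t_cross = 360.0
    p2 = second_regime_parameters(p1, t_cross, b2=900.0)
    temps = np.arange(312.0, 421.0, 4.0)
    tau = np.where(
        temps <= t_cross, vft_tau(temps, p1), vft_tau(np.clip(temps, 311, None), p2)
    )
    sr = detect_crossover(stickel_transform(RelaxationMap(temps, tau)))
    assert sr.t_cross == pytest.approx(t_cross, abs=3.0)
    assert len(sr.segments) == 2


def test_second_regime_is_tau_continuous():
    p1 = VFT_PRESETS["SVT"].vft
    p2 = second_regime_parameters(p1, 360.0, b2=900.0)
    assert vft_tau(360.0, p2) == pytest.approx(vft_tau(360.0, p1), rel=1e-9)


def test_noisy_transform_stays_positive():
    p = VFT_PRESETS["SVT"].vft
    rmap = _map_from(p, n=20)
    rng = np.random.default_rng(3)
    noisy = rmap.tau_alpha * 10 ** rng.normal(0.0, 0.01, rmap.tau_alpha.shape)
    sr = stickel_transform(RelaxationMap(rmap.temperature, np.sort(noisy)[::-1]))
    assert np.all(sr.phi > 0)
    assert np.all(np.isfinite(sr.phi))


def test_relaxation_map_validation():
    with pytest.raises(ValueError):
        RelaxationMap(np.array([300.0, 300.0, 310.0, 320.0]), np.ones(4))
    with pytest.raises(ValueError):
        RelaxationMap(np.array([300.0, 310.0]), np.array([1.0, -1.0]))
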