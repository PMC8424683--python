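"""Schröder–Van Laar liquidus curves and eutectic solvers vs independent
grid-scan / root-bracketing oracles."""

import numpy as np
import pytest
from scipy.optimize import bisect

from pharmglass.components import PureComponent
from pharmglass.phase import (
    GAS_CONSTANT,
    NoEutecticError,
    assemble_experimental_diagram,
    binary_eutectic,
    expected_endotherm_count,
    liquidus_surface,
    svl_liquidus,
    ternary_eutectic,
    theoretical_binary_diagram,
)

from conftest import random_component


# --- svl_liquidus -----------------------------------------------------------

def test_pure_component_melts_at_t0(simple_pair):
    a, _ = simple_pair
    assert svl_liquidus(1.0, a) == a.melt_temperature


def test_svl_matches_bisection_oracle(simple_pair):
    a, _ = simple_pair
    x = 0.5

    def residual(temp):
        return np.log(x) + a.fusion_enthalpy / GAS_CONSTANT * (
            1.0 / temp - 1.0 / a.melt_temperature
        )

    t_oracle = bisect(residual, 100.0, a.melt_temperature, xtol=1e-10)
    assert svl_liquidus(x, a) == pytest.approx(t_oracle, abs=1e-7)


def test_svl_strictly_increasing_in_x(simple_pair):
    a, _ = simple_pair
    xs = np.linspace(0.05, 1.0, 200)
    temps = svl_liquidus(xs, a)
    assert np.all(np.diff(temps) > 0)


def test_svl_domain_errors(simple_pair):
    a, _ = simple_pair
    with pytest.raises(ValueError):
        svl_liquidus(0.0, a)
    with pytest.raises(ValueError):
        svl_liquidus(1.5, a)


# --- binary eutectic --------------------------------------------------------

def _binary_grid_oracle(a, b, n=100_000):
    xs = np.linspace(1e-6, 1 - 1e-6, n)
    gap = np.abs(svl_liquidus(xs, a) - svl_liquidus(1.0 - xs, b))
    k = int(np.argmin(gap))
    return xs[k], 1.0 / n


def test_identical_components_eutectic_at_half(simple_pair):
    a, _ = simple_pair
    x_e, t_e = binary_eutectic(a, a)
    assert x_e == pytest.approx(0.5, abs=1e-9)
    assert t_e < a.melt_temperature


def test_binary_eutectic_matches_grid_oracle(simple_pair):
    a, b = simple_pair
    x_e, t_e = binary_eutectic(a, b)
    x_oracle, dx = _binary_grid_oracle(a, b)
    assert abs(x_e - x_oracle) <= dx
    assert t_e < min(a.melt_temperature, b.melt_temperature)


def test_binary_eutectic_randomized_vs_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        a = random_component(rng, "A")
        b = random_component(rng, "B")
        x_e, t_e = binary_eutectic(a, b)
        x_oracle, dx = _binary_grid_oracle(a, b)
        assert abs(x_e - x_oracle) <= dx
        assert t_e <= min(a.melt_temperature, b.melt_temperature)


# --- ternary eutectic -------------------------------------------------------

def _ternary_grid_oracle(a, b, c, step=0.005):
    n = int(round(1.0 / step))
    i, j = np.meshgrid(np.arange(1, n), np.arange(1, n), indexing="ij")
    mask = (i + j) < n
    xa, xb = i[mask] / n, j[mask] / n
    xc = 1.0 - xa - xb
    surf = np.maximum(
        np.maximum(svl_liquidus(xa, a), svl_liquidus(xb, b)), svl_liquidus(xc, c)
    )
    k = int(np.argmin(surf))
    return np.array([xa[k], xb[k], xc[k]]), step


def test_identical_triple_eutectic_at_third(simple_pair):
    a, _ = simple_pair
    xa, xb, xc, t_e = ternary_eutectic(a, a, a)
    assert np.allclose([xa, xb, xc], 1.0 / 3.0, atol=1e-6)
    assert t_e < a.melt_temperature


def test_ternary_eutectic_matches_grid_oracle(simple_triple):
    a, b, c = simple_triple
    xa, xb, xc, t_e = ternary_eutectic(a, b, c)
    x_oracle, step = _ternary_grid_oracle(a, b, c)
    assert np.max(np.abs(np.array([xa, xb]) - x_oracle[:2])) <= step
    assert abs(xc - x_oracle[2]) <= 2 * step
    assert t_e <= min(comp.melt_temperature for comp in (a, b, c))


def test_low_melting_component_dominates_eutectic():
    a = PureComponent("A", 100.0, 430.0, 35000.0)
    b = PureComponent("B", 100.0, 420.0, 38000.0)
    c = PureComponent("C", 100.0, 370.0, 20000.0)  # low T0, low dHfus
    xa, xb, xc, _ = ternary_eutectic(a, b, c)
    x_oracle, step = _ternary_grid_oracle(a, b, c)
    assert xc > xa and xc > xb
    # grid argmin localises the two independent coordinates to one step
    # each; the dependent third coordinate absorbs both errors
    assert np.max(np.abs(np.array([xa, xb]) - x_oracle[:2])) <= step
    assert abs(xc - x_oracle[2]) <= 2 * step


def test_ternary_te_below_all_binary_te(simple_triple):
    a, b, c = simple_triple
    t3 = ternary_eutectic(a, b, c)[3]
    for pair in [(a, b), (a, c), (b, c)]:
        assert t3 <= binary_eutectic(*pair)[1] + 1e-9


def test_liquidus_surface_is_max_of_branches(simple_triple):
    grid = liquidus_surface(simple_triple, grid_step=0.05)
    a, b, c = simple_triple
    row = grid.iloc[100]
    branch = [
        svl_liquidus(row.x1, a),
        svl_liquidus(row.x2, b),
        svl_liquidus(row.x3, c),
    ]
    assert row.T_liquidus_K == pytest.approx(max(branch))
    assert int(row.governing_component) == int(np.argmax(branch))


# --- endotherm count --------------------------------------------------------

def test_endotherm_count_binary(simple_pair):
    a, b = simple_pair
    x_e, _ = binary_eutectic(a, b)
    assert expected_endotherm_count([x_e, 1 - x_e], [a, b]) == 1
    assert expected_endotherm_count([0.8, 0.2], [a, b]) == 2


def test_endotherm_count_ternary_off_eutectic(simple_triple):
    # composition far from the eutectic: all three branches above T_e
    a, b, c = simple_triple
    xa, xb, xc, _ = ternary_eutectic(a, b, c)
    assert expected_endotherm_count([xa, xb, xc], [a, b, c]) == 1
    # two branches above the eutectic temperature: eutectic melt plus two
    # dissolution endotherms
    assert expected_endotherm_count([0.35, 0.35, 0.30], simple_triple) == 3


# --- experimental assembly --------------------------------------------------

def test_single_endotherm_record_is_the_eutectic(simple_pair):
    a, b = simple_pair
    records = [
        ([0.8, 0.2], 335.0, 380.0),
        ([0.3, 0.7], 336.0, 336.5),  # single endotherm
        ([0.5, 0.5], 335.5, 360.0),
    ]
    diagram = assemble_experimental_diagram(records, [a, b])
    assert diagram.eutectic[0] == pytest.approx(0.3)
    assert diagram.eutectic[1] == pytest.approx(336.5)


def test_recovers_eutectic_from_svl_sampled_records(simple_pair):
    a, b = simple_pair
    x_e, t_e = binary_eutectic(a, b)
    xs = np.round(np.linspace(0.05, 0.95, 19), 3)
    records = []
    for x in xs:
        liq = max(svl_liquidus(x, a), svl_liquidus(1 - x, b))
        records.append(([x, 1 - x], t_e, liq))
    diagram = assemble_experimental_diagram(records, [a, b])
    step = xs[1] - xs[0]
    assert abs(diagram.eutectic[0] - x_e) <= step


def test_all_liquidus_missing_rejected(simple_pair):
    records = [([0.5, 0.5], 300.0, None)] * 4
    with pytest.raises(ValueError):
        assemble_experimental_diagram(records, list(simple_pair))


def test_no_eutectic_signal():
    # B's branch stays far above A's everywhere: no crossing on (0, 1)
    a = PureComponent("A", 100.0, 400.0, 1e5)
    b = PureComponent("B", 100.0, 700.0, 1e6)
    with pytest.raises(NoEutecticError):
        binary_eutectic(a, b)


def test_theoretical_binary_diagram_branches_meet(simple_pair):
    a, b = simple_pair
    d = theoretical_binary_diagram(a, b)
    x_e, t_e = d.eutectic
    for name, branch in d.branches.items():
        xs = [p[0] for p in branch]
        temps = [p[1] for p in branch]
        assert temps == sorted(temps)  # monotone toward the pure melt
        assert min(temps) == pytest.approx(t_e, abs=1e-6)
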