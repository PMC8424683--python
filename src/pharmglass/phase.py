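"""Ideal-solution liquidus curves and eutectic points.

The Schröder–Van Laar (SVL) equation for an ideal melt relates the mole
fraction ``x`` of a component to the temperature ``T`` at which its crystal
is in equilibrium with the liquid:

    ln x = -(ΔH0 / R) * (1/T - 1/T0)

with ΔH0 the enthalpy of fusion (J/mol), T0 the pure-component melting
point (K) and R the gas constant.  Solved for T this gives the liquidus
branch of that component; branches of all components intersect at the
eutectic, the lowest-melting composition of the mixture.

The solvers here are purely thermodynamic (no activity coefficients),
matching the bare SVL form.  Binary eutectics are found by bracketed root
finding, ternary eutectics by a two-variable root solve on the composition
simplex with a barycentric grid-scan fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .components import Composition, PureComponent, weight_to_mole

__all__ = [
    "GAS_CONSTANT",
    "svl_liquidus",
    "binary_eutectic",
    "ternary_eutectic",
    "liquidus_surface",
    "theoretical_binary_diagram",
    "theoretical_ternary_diagram",
    "expected_endotherm_count",
    "assemble_experimental_diagram",
    "BinaryDiagram",
    "TernaryDiagram",
    "NoEutecticError",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


class NoEutecticError(RuntimeError):
    """Raised when liquidus branches do not intersect inside the simplex."""


def svl_liquidus(x, comp: PureComponent):
    """Liquidus temperature of ``comp`` at melt mole fraction ``x``.

    Closed form of the SVL equation: 1/T = 1/T0 - R ln(x) / ΔH0.
    Accepts scalars or arrays; ``x`` must satisfy 0 < x <= 1.

    Raises
    ------
    ValueError
        If any ``x`` is outside (0, 1], or so small that the computed
        inverse temperature is non-positive (the ideal law breaks down).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0) or np.any(x_arr > 1):
        raise ValueError(f"mole fraction must be in (0, 1], got {x}")
    inv_t = 1.0 / comp.melt_temperature - GAS_CONSTANT * np.log(x_arr) / comp.fusion_enthalpy
    if np.any(inv_t <= 0):
        raise ValueError(
            f"x too small for the ideal liquidus of {comp.name}: 1/T <= 0"
        )
    t = 1.0 / inv_t
    return float(t) if np.isscalar(x) or x_arr.ndim == 0 else t


def binary_eutectic(
    a: PureComponent, b: PureComponent, *, xtol: float = 1e-12
) -> tuple[float, float]:
    """Eutectic of a binary ideal mixture.

    Returns ``(x_e, T_e)`` where ``x_e`` is the mole fraction of ``a`` at
    which the two SVL branches cross and ``T_e`` their common temperature.
    Brent bracketing on [1e-6, 1-1e-6]; the temperature mismatch at the
    root is below 1e-6 K.
    """

    def gap(x: float) -> float:
        return svl_liquidus(x, a) - svl_liquidus(1.0 - x, b)

    lo, hi = 1e-6, 1.0 - 1e-6
    try:
        g_lo, g_hi = gap(lo), gap(hi)
    except ValueError as exc:  # branch leaves the physical domain
        raise NoEutecticError(str(exc)) from exc
    if g_lo * g_hi > 0:
        raise NoEutecticError(
            f"SVL branches of {a.name} and {b.name} do not cross on (0, 1)"
        )
    x_e = optimize.brentq(gap, lo, hi, xtol=xtol)
    t_e = 0.5 * (svl_liquidus(x_e, a) + svl_liquidus(1.0 - x_e, b))
    assert abs(gap(x_e)) < 1e-6
    return float(x_e), float(t_e)


def _branch_temps(x: np.ndarray, comps: Sequence[PureComponent]) -> np.ndarray:
    """Per-component SVL temperatures at composition x (fractions of each)."""
    return np.array([svl_liquidus(xi, c) for xi, c in zip(x, comps)])


def _surface_arrays(
    comps: Sequence[PureComponent], grid_step: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized barycentric grid of the ternary liquidus surface.

    Returns flat arrays (x_a, x_b, T_surface) over interior grid points;
    the surface temperature is the max of the three SVL branches.
    """
    n = int(round(1.0 / grid_step))
    i, j = np.meshgrid(np.arange(1, n), np.arange(1, n), indexing="ij")
    mask = (i + j) < n
    xa = i[mask] / n
    xb = j[mask] / n
    xc = 1.0 - xa - xb
    ta = svl_liquidus(xa, comps[0])
    tb = svl_liquidus(xb, comps[1])
    tc = svl_liquidus(xc, comps[2])
    return xa, xb, np.maximum(np.maximum(ta, tb), tc)


def ternary_eutectic(
    a: PureComponent,
    b: PureComponent,
    c: PureComponent,
    *,
    grid_step: float = 0.005,
) -> tuple[float, float, float, float]:
    """Eutectic composition and temperature of a ternary ideal mixture.

    Solves T_a(x_a) = T_b(x_b) = T_c(1 - x_a - x_b) as a two-variable root
    problem seeded from a barycentric grid scan; falls back to the grid
    optimum if the root solver leaves the simplex.  Returns
    ``(x_a, x_b, x_c, T_e)`` with the temperature residual below 1e-6 K.
    """
    comps = (a, b, c)

    # vectorized grid scan of the liquidus surface for a robust seed
    xa_grid, xb_grid, t_grid = _surface_arrays(comps, grid_step)
    k_min = int(np.argmin(t_grid))
    x0 = np.array([xa_grid[k_min], xb_grid[k_min]])
    t_seed = float(t_grid[k_min])

    def residuals(v: np.ndarray) -> np.ndarray:
        xa, xb = v
        xc = 1.0 - xa - xb
        if min(xa, xb, xc) <= 0 or max(xa, xb, xc) >= 1:
            return np.array([1e6, 1e6])
        ta, tb, tc = _branch_temps(np.array([xa, xb, xc]), comps)
        return np.array([ta - tb, tb - tc])

    sol = optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    xa, xb = sol.x
    xc = 1.0 - xa - xb
    if (
        min(xa, xb, xc) <= 0
        or np.max(np.abs(residuals(sol.x))) > 1e-6
    ):
        raise NoEutecticError(
            "ternary eutectic solve left the simplex or did not converge; "
            f"residuals {residuals(sol.x)}, grid seed {x0} at {t_seed:.2f} K"
        )
    t_e = float(_branch_temps(np.array([xa, xb, xc]), comps).max())
    return float(xa), float(xb), float(xc), t_e


def liquidus_surface(
    components: Sequence[PureComponent], *, grid_step: float = 0.01
) -> pd.DataFrame:
    """Ternary liquidus surface on a barycentric grid.

    At each composition the liquidus is the *highest* of the three SVL
    branch temperatures (the last crystal to dissolve governs), recorded
    together with the governing component index.  Columns: x1, x2, x3,
    T_liquidus_K, governing_component.
    """
    if len(components) != 3:
        raise ValueError("liquidus_surface expects exactly three components")
    xa, xb, _ = _surface_arrays(components, grid_step)
    xc = 1.0 - xa - xb
    temps = np.vstack(
        [
            svl_liquidus(xa, components[0]),
            svl_liquidus(xb, components[1]),
            svl_liquidus(xc, components[2]),
        ]
    )
    governing = np.argmax(temps, axis=0)
    return pd.DataFrame(
        {
            "x1": xa,
            "x2": xb,
            "x3": xc,
            "T_liquidus_K": temps[governing, np.arange(xa.size)],
            "governing_component": governing,
        }
    )


@dataclass
class BinaryDiagram:
    """Binary phase diagram: per-component liquidus branches and eutectic."""

    components: tuple[PureComponent, PureComponent]
    branches: dict[str, list[tuple[float, float]]]  # name -> [(x_own, T), ...]
    eutectic: tuple[float, float]  # (x of first component, T_e)
    solidus_temperature: float | None = None

    @property
    def eutectic_temperature(self) -> float:
        return self.eutectic[1]


@dataclass
class TernaryDiagram:
    """Ternary phase diagram: liquidus surface grid and eutectic point."""

    components: tuple[PureComponent, PureComponent, PureComponent]
    grid: pd.DataFrame
    eutectic: tuple[float, float, float, float]  # (x1, x2, x3, T_e)

    @property
    def eutectic_temperature(self) -> float:
        return self.eutectic[3]


def theoretical_binary_diagram(
    a: PureComponent, b: PureComponent, *, n_points: int = 101
) -> BinaryDiagram:
    """SVL-predicted binary diagram with both branches sampled to the eutectic."""
    x_e, t_e = binary_eutectic(a, b)
    xs_a = np.linspace(x_e, 1.0, n_points)
    xs_b = np.linspace(1.0 - x_e, 1.0, n_points)
    branches = {
        a.name: [(float(x), float(svl_liquidus(x, a))) for x in xs_a],
        b.name: [(float(x), float(svl_liquidus(x, b))) for x in xs_b],
    }
    return BinaryDiagram(components=(a, b), branches=branches, eutectic=(x_e, t_e))


def theoretical_ternary_diagram(
    a: PureComponent,
    b: PureComponent,
    c: PureComponent,
    *,
    grid_step: float = 0.01,
) -> TernaryDiagram:
    """SVL-predicted ternary diagram (surface grid plus eutectic point)."""
    eut = ternary_eutectic(a, b, c)
    grid = liquidus_surface((a, b, c), grid_step=grid_step)
    return TernaryDiagram(components=(a, b, c), grid=grid, eutectic=eut)


def expected_endotherm_count(
    mole_fractions: Sequence[float],
    components: Sequence[PureComponent],
    *,
    resolve_tol: float = 1.0,
) -> int:
    """Number of melting endotherms a DSC scan of this composition shows.

    At the eutectic a single event appears.  Away from it, the eutectic
    melt is followed by dissolution of each component whose liquidus branch
    at this composition lies more than ``resolve_tol`` K above the eutectic
    temperature: the count is 1 plus the number of such components.
    """
    x = np.asarray(mole_fractions, dtype=float)
    if np.any(x <= 0) or abs(x.sum() - 1.0) > 1e-6:
        raise ValueError("composition must be interior to the simplex and sum to 1")
    if len(components) == 2:
        _, t_e = binary_eutectic(components[0], components[1])
    elif len(components) == 3:
        t_e = ternary_eutectic(*components)[3]
    else:
        raise ValueError("expected 2 or 3 components")
    temps = _branch_temps(x, components)
    above = int(np.sum(temps > t_e + resolve_tol))
    return 1 + above if above > 0 else 1


def assemble_experimental_diagram(
    records: Sequence[tuple[Sequence[float], float | None, float | None]],
    components: Sequence[PureComponent],
    *,
    single_endotherm_tol: float = 2.0,
):
    """Build a phase diagram from DSC-derived (composition, solidus, liquidus) rows.

    ``records`` holds, per measured sample, the mole-fraction composition,
    the solidus temperature (onset of first endotherm) and the liquidus
    temperature (peak of the last) — either may be None when not resolved.
    The experimental eutectic is the composition whose solidus and liquidus
    coincide within ``single_endotherm_tol`` K (a single endotherm); absent
    one, it is taken from the interpolated intersection of the liquidus
    branches (binary) or the grid minimum of liquidus (ternary).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to assemble a diagram")
    liq_known = [(np.asarray(x, float), s, l) for x, s, l in records if l is not None]
    if not liq_known:
        raise ValueError("all liquidus temperatures missing")

    # single-endotherm candidates: solidus == liquidus within tolerance
    singles = [
        (x, l)
        for x, s, l in liq_known
        if s is not None and abs(l - s) < single_endotherm_tol
    ]

    if len(components) == 2:
        a, b = components
        if singles:
            x_e = float(singles[0][0][0])
            t_e = float(singles[0][1])
        else:
            # branch intersection from interpolated experimental liquidus
            xs = np.array([x[0] for x, _, _ in liq_known])
            ts = np.array([l for _, _, l in liq_known])
            order = np.argsort(xs)
            xs, ts = xs[order], ts[order]
            i_min = int(np.argmin(ts))
            x_e, t_e = float(xs[i_min]), float(ts[i_min])
        branches = {
            a.name: [(float(x[0]), float(l)) for x, _, l in liq_known if x[0] >= x_e],
            b.name: [(float(1 - x[0]), float(l)) for x, _, l in liq_known if x[0] <= x_e],
        }
        solidus_vals = [s for _, s, _ in liq_known if s is not None]
        return BinaryDiagram(
            components=(a, b),
            branches=branches,
            eutectic=(x_e, t_e),
            solidus_temperature=float(np.median(solidus_vals)) if solidus_vals else None,
        )

    if len(components) != 3:
        raise ValueError("expected 2 or 3 components")
    grid = pd.DataFrame(
        [
            (x[0], x[1], x[2], l, -1)
            for x, _, l in liq_known
        ],
        columns=["x1", "x2", "x3", "T_liquidus_K", "governing_component"],
    )
    if singles:
        x = singles[0][0]
        eut = (float(x[0]), float(x[1]), float(x[2]), float(singles[0][1]))
    else:
        i_min = int(grid["T_liquidus_K"].idxmin())
        row = grid.loc[i_min]
        eut = (float(row.x1), float(row.x2), float(row.x3), float(row.T_liquidus_K))
    return TernaryDiagram(
        components=tuple(components), grid=grid, eutectic=eut
    )
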