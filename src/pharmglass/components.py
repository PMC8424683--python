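"""Pure-component thermodynamic records and composition conversions.

A :class:`PureComponent` carries the three constants the ideal-solution
(Schröder–Van Laar) liquidus needs — molar mass, melting point and enthalpy
of fusion — plus, optionally, the glass transition temperature of the
amorphous form, which the synthetic DSC generator uses for mixture-Tg
estimates.

Compositions of a mixture are held in both weight- and mole-fraction form;
the two are kept mutually consistent through the component molar masses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PureComponent",
    "Composition",
    "weight_to_mole",
    "mole_to_weight",
    "load_component_registry",
    "save_component_registry",
]

_FRACTION_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PureComponent:
    """Thermodynamic identity of one drug.

    Parameters
    ----------
    name : str
        Component label (e.g. ``"EZB"``).
    molar_mass : float
        Molar mass in g/mol.
    melt_temperature : float
        Melting point T0 of the pure crystal in K.
    fusion_enthalpy : float
        Enthalpy of fusion ΔH0 in J/mol.
    glass_tg : float, optional
        Calorimetric glass transition of the amorphous form in K.
    """

    name: str
    molar_mass: float
    melt_temperature: float
    fusion_enthalpy: float
    glass_tg: float | None = None

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")
        if not self.melt_temperature > 0:
            raise ValueError(
                f"melt_temperature must be > 0, got {self.melt_temperature}"
            )
        if not self.fusion_enthalpy > 0:
            raise ValueError(
                f"fusion_enthalpy must be > 0, got {self.fusion_enthalpy}"
            )


def _check_fractions(fracs: np.ndarray, what: str) -> np.ndarray:
    fracs = np.asarray(fracs, dtype=float)
    if np.any(fracs < 0) or np.any(fracs > 1):
        raise ValueError(f"{what} must lie in [0, 1], got {fracs}")
    total = fracs.sum()
    if abs(total - 1.0) > _FRACTION_SUM_TOL:
        raise ValueError(f"{what} must sum to 1 (got {total:.8f})")
    return fracs / total


def weight_to_mole(
    weight_fractions: Sequence[float], molar_masses: Sequence[float]
) -> np.ndarray:
    """Convert weight fractions to mole fractions.

    x_i = (w_i / M_i) / sum_j (w_j / M_j).  Raises ``ValueError`` on
    non-positive molar masses or fractions not summing to 1.
    """
    masses = np.asarray(molar_masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError(f"molar masses must be > 0, got {masses}")
    w = _check_fractions(np.asarray(weight_fractions, dtype=float), "weight fractions")
    if w.shape != masses.shape:
        raise ValueError("weight_fractions and molar_masses length mismatch")
    moles = w / masses
    return moles / moles.sum()


def mole_to_weight(
    mole_fractions: Sequence[float], molar_masses: Sequence[float]
) -> np.ndarray:
    """Convert mole fractions to weight fractions (inverse of weight_to_mole)."""
    masses = np.asarray(molar_masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError(f"molar masses must be > 0, got {masses}")
    x = _check_fractions(np.asarray(mole_fractions, dtype=float), "mole fractions")
    if x.shape != masses.shape:
        raise ValueError("mole_fractions and molar_masses length mismatch")
    grams = x * masses
    return grams / grams.sum()


@dataclass(frozen=True)
class Composition:
    """A mixture composition in both weight- and mole-fraction representation."""

    names: tuple[str, ...]
    weight_fractions: tuple[float, ...]
    mole_fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_fractions(np.array(self.weight_fractions), "weight fractions")
        _check_fractions(np.array(self.mole_fractions), "mole fractions")
        if not len(self.names) == len(self.weight_fractions) == len(self.mole_fractions):
            raise ValueError("names and fraction lists must have equal length")

    @classmethod
    def from_weight(
        cls, weights: Sequence[float], components: Sequence[PureComponent]
    ) -> "Composition":
        masses = [c.molar_mass for c in components]
        x = weight_to_mole(weights, masses)
        return cls(
            names=tuple(c.name for c in components),
            weight_fractions=tuple(float(v) for v in np.asarray(weights, float)),
            mole_fractions=tuple(float(v) for v in x),
        )

    @classmethod
    def from_mole(
        cls, moles: Sequence[float], components: Sequence[PureComponent]
    ) -> "Composition":
        masses = [c.molar_mass for c in components]
        w = mole_to_weight(moles, masses)
        return cls(
            names=tuple(c.name for c in components),
            weight_fractions=tuple(float(v) for v in w),
            mole_fractions=tuple(float(v) for v in np.asarray(moles, float)),
        )

    def __len__(self) -> int:
        return len(self.names)


def load_component_registry(path: str | Path) -> dict[str, PureComponent]:
    """Read a component registry from JSON or CSV.

    JSON: list of objects with keys ``name``, ``molar_mass_g_mol``, ``Tm_K``,
    ``dHfus_J_mol`` and optionally ``Tg_K``.  CSV: same column names.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records: Iterable[dict] = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    registry: dict[str, PureComponent] = {}
    for rec in records:
        tg = rec.get("Tg_K")
        if tg is not None and not np.isfinite(tg):
            tg = None
        comp = PureComponent(
            name=str(rec["name"]),
            molar_mass=float(rec["molar_mass_g_mol"]),
            melt_temperature=float(rec["Tm_K"]),
            fusion_enthalpy=float(rec["dHfus_J_mol"]),
            glass_tg=None if tg is None else float(tg),
        )
        registry[comp.name] = comp
    return registry


def save_component_registry(
    components: Iterable[PureComponent], path: str | Path
) -> None:
    """Write components to a JSON registry file."""
    path = Path(path)
    recs = [
        {
            "name": c.name,
            "molar_mass_g_mol": c.molar_mass,
            "Tm_K": c.melt_temperature,
            "dHfus_J_mol": c.fusion_enthalpy,
            "Tg_K": c.glass_tg,
        }
        for c in components
    ]
    path.write_text(json.dumps(recs, indent=2))
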