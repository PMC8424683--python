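"""Literature parameter presets for the ezetimibe (EZB) / simvastatin (SVT)
/ fenofibrate (FEN) ternary system.

Two kinds of constants live here:

* **Reported dynamics parameters** (`VFT_PRESETS`): published VFT fitting
  parameters of the neat amorphous drugs and their ternary mixtures
  (sample labels are EZB/SVT/FEN mass ratios), together with the reported
  calorimetric Tg, kinetic Tg, fragility, crossover temperature and the
  isochronal temperature T(τ_α = 0.63 μs).  These are *inputs*: the
  package recomputes the derived columns from the VFT parameters and they
  seed the synthetic spectrum generator.  Two entries carry
  ``consistent=False``: the neat-EZB derived columns are not reproduced by
  inverting its printed VFT parameters, and the 10/40/50 row prints a
  Vogel temperature above its own Tg — both are excluded from validation.

* **Crystallization presets** (`CRYSTALLIZATION_PRESETS`): reported
  isothermal half-lives at T(τ_α = 0.63 μs), used by the synthetic
  kinetics generator.

* **Component constants** (`COMPONENT_PRESETS`): molar masses are the
  published values; the melting points and fusion enthalpies are
  *literature placeholder values* (the thermodynamic constants used for
  the published phase diagrams were not tabulated) and are intended to be
  replaced by the user's own calibration.  Phase-diagram validation in
  this package therefore uses synthetic constants, never these.
"""

from __future__ import annotations

from dataclasses import dataclass

from .components import PureComponent
from .relaxation import VFTParameters

__all__ = [
    "VFTPreset",
    "VFT_PRESETS",
    "CrystallizationPreset",
    "CRYSTALLIZATION_PRESETS",
    "COMPONENT_PRESETS",
]


@dataclass(frozen=True)
class VFTPreset:
    """One sample's published dynamics entry (EZB/SVT/FEN mass ratio label)."""

    label: str
    vft: VFTParameters
    tg_dsc: float  # K, calorimetric (10 K/min)
    tg_bds: float  # K, reported kinetic Tg = T(tau = 100 s)
    fragility: float  # reported steepness index m_p
    t_cross: float | None  # K, VFT1/VFT2 crossover; None = single VFT
    t_isochronal: float  # K, reported T(tau = 0.63 us)
    consistent: bool = True  # False: internally inconsistent, excluded from checks


VFT_PRESETS: dict[str, VFTPreset] = {
    p.label: p
    for p in [
        VFTPreset(
            "EZB",
            VFTParameters(-11.81, 1130.0, 301.1),
            tg_dsc=336, tg_bds=333, fragility=93, t_cross=355, t_isochronal=388,
            consistent=False,  # printed Tg/m_p not reproduced by these parameters
        ),
        VFTPreset(
            "SVT",
            VFTParameters(-15.68, 2386.0, 244.0),
            tg_dsc=305, tg_bds=303, fragility=91, t_cross=None, t_isochronal=353,
        ),
        VFTPreset(
            "FEN",
            VFTParameters(-13.52, 1465.0, 209.3),
            tg_dsc=254, tg_bds=251, fragility=95, t_cross=None, t_isochronal=298,
        ),
        VFTPreset(
            "70/10/20",
            VFTParameters(-12.51, 1483.0, 266.5),
            tg_dsc=313, tg_bds=311, fragility=102, t_cross=395, t_isochronal=369,
        ),
        VFTPreset(
            "40/40/20",
            VFTParameters(-12.93, 1576.0, 256.4),
            tg_dsc=302, tg_bds=301, fragility=104, t_cross=382, t_isochronal=357,
        ),
        VFTPreset(
            "10/70/20",
            VFTParameters(-13.78, 1769.0, 242.4),
            tg_dsc=291, tg_bds=290, fragility=98, t_cross=368, t_isochronal=343,
        ),
        VFTPreset(
            "30/30/40",
            VFTParameters(-12.75, 1514.0, 240.1),
            tg_dsc=285, tg_bds=284, fragility=97, t_cross=355, t_isochronal=340,
        ),
        VFTPreset(
            "40/10/50",
            VFTParameters(-12.79, 1564.0, 237.1),
            tg_dsc=283, tg_bds=282, fragility=95, t_cross=361, t_isochronal=340,
        ),
        VFTPreset(
            "10/40/50",
            VFTParameters(-13.18, 1553.0, 277.7),
            tg_dsc=272, tg_bds=271, fragility=98, t_cross=344, t_isochronal=325,
            consistent=False,  # printed T0 exceeds Tg: physically impossible
        ),
        VFTPreset(
            "10/20/70",  # ternary eutectic composition
            VFTParameters(-12.57, 1346.0, 223.1),
            tg_dsc=265, tg_bds=263, fragility=97, t_cross=None, t_isochronal=315,
        ),
        VFTPreset(
            "5.3/10.5/84.2",  # therapeutic composition
            VFTParameters(-12.55, 1280.0, 219.0),
            tg_dsc=260, tg_bds=257, fragility=99, t_cross=None, t_isochronal=307,
        ),
    ]
}


@dataclass(frozen=True)
class CrystallizationPreset:
    """Reported isothermal crystallization kinetics at T(τ_α = 0.63 μs)."""

    label: str
    temperature: float  # K
    half_life_s: float
    endset_s: float | None = None


_MIN = 60.0
_HR = 3600.0

CRYSTALLIZATION_PRESETS: dict[str, CrystallizationPreset] = {
    p.label: p
    for p in [
        CrystallizationPreset("EZB", 388.0, 79 * _MIN, 2 * _HR),
        CrystallizationPreset("FEN", 298.0, 114 * _MIN, 4 * _HR),
        CrystallizationPreset("SVT", 353.0, 330 * _MIN, 25 * _HR),
        CrystallizationPreset("5.3/10.5/84.2", 307.0, 10.5 * _HR, 13.5 * _HR),
    ]
}


# Molar masses are published; Tm / dHfus are literature placeholders
# (user-replaceable) — see the module docstring.  glass_tg values are the
# reported calorimetric Tg of the quench-cooled amorphous drugs.
COMPONENT_PRESETS: dict[str, PureComponent] = {
    c.name: c
    for c in [
        PureComponent("EZB", molar_mass=409.4, melt_temperature=436.0,
                      fusion_enthalpy=34000.0, glass_tg=336.0),
        PureComponent("SVT", molar_mass=418.6, melt_temperature=412.0,
                      fusion_enthalpy=29500.0, glass_tg=306.0),
        PureComponent("FEN", molar_mass=360.83, melt_temperature=353.6,
                      fusion_enthalpy=33100.0, glass_tg=254.0),
    ]
}
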