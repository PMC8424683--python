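"""CSV dialects for instrument-style data plus ground-truth sidecars.

All files are plain CSV with ``# key: value`` metadata header lines, so
they survive text-only pipelines and diff cleanly.  Generators may attach
a ground-truth sidecar ``<stem>.truth.json`` next to any data file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crystallization import CrystallizationSeries
from .dielectric import DielectricSpectrum
from .dsc import Thermogram
from .relaxation import RelaxationMap

__all__ = [
    "read_thermogram",
    "write_thermogram",
    "read_spectrum",
    "write_spectrum",
    "read_relaxation_map",
    "write_relaxation_map",
    "read_crystallization",
    "write_crystallization",
    "write_truth_sidecar",
    "read_truth_sidecar",
]


def _read_with_meta(path: Path) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if ":" in line:
                    key, _, val = line.lstrip("#").partition(":")
                    meta[key.strip()] = val.strip()
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    return meta, df


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _write_with_meta(path: Path, meta: dict, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    meta = {"heating_rate_K_min": tg.heating_rate}
    if tg.sample_mass is not None:
        meta["sample_mass_mg"] = tg.sample_mass
    df = pd.DataFrame(
        {"temperature_K": tg.temperature, "heat_flow": tg.heat_flow}
    )
    _write_with_meta(Path(path), meta, df)


def read_thermogram(path: str | Path, *, heating_rate: float | None = None) -> Thermogram:
    path = Path(path)
    meta, df = _read_with_meta(path)
    _require_columns(df, ["temperature_K", "heat_flow"], path)
    rate = heating_rate if heating_rate is not None else float(
        meta.get("heating_rate_K_min", "nan")
    )
    if not np.isfinite(rate):
        raise ValueError(f"{path}: heating rate missing from metadata and argument")
    mass = meta.get("sample_mass_mg")
    return Thermogram(
        temperature=df["temperature_K"].to_numpy(),
        heat_flow=df["heat_flow"].to_numpy(),
        heating_rate=rate,
        sample_mass=float(mass) if mass else None,
    )


def write_spectrum(spec: DielectricSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "freq_Hz": spec.frequency,
            "eps_real": spec.eps_real,
            "eps_imag": spec.eps_imag,
        }
    )
    _write_with_meta(Path(path), {"temperature_K": spec.temperature}, df)


def read_spectrum(path: str | Path, *, temperature: float | None = None) -> DielectricSpectrum:
    path = Path(path)
    meta, df = _read_with_meta(path)
    _require_columns(df, ["freq_Hz", "eps_real", "eps_imag"], path)
    temp = temperature if temperature is not None else float(
        meta.get("temperature_K", "nan")
    )
    if not np.isfinite(temp):
        raise ValueError(f"{path}: temperature missing from metadata and argument")
    return DielectricSpectrum(
        frequency=df["freq_Hz"].to_numpy(),
        eps_real=df["eps_real"].to_numpy(),
        eps_imag=df["eps_imag"].to_numpy(),
        temperature=temp,
    )


def write_relaxation_map(rmap: RelaxationMap, path: str | Path) -> None:
    df = pd.DataFrame({"T_K": rmap.temperature, "tau_s": rmap.tau_alpha})
    _write_with_meta(Path(path), {"sample": rmap.sample_label}, df)


def read_relaxation_map(path: str | Path) -> RelaxationMap:
    path = Path(path)
    meta, df = _read_with_meta(path)
    _require_columns(df, ["T_K", "tau_s"], path)
    return RelaxationMap(
        temperature=df["T_K"].to_numpy(),
        tau_alpha=df["tau_s"].to_numpy(),
        sample_label=meta.get("sample", ""),
    )


def write_crystallization(cs: CrystallizationSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": cs.time, "eps_prime": cs.eps_static})
    _write_with_meta(
        Path(path),
        {"temperature_K": cs.temperature, "sample": cs.sample_label},
        df,
    )


def read_crystallization(path: str | Path) -> CrystallizationSeries:
    path = Path(path)
    meta, df = _read_with_meta(path)
    _require_columns(df, ["time_s", "eps_prime"], path)
    return CrystallizationSeries(
        time=df["time_s"].to_numpy(),
        eps_static=df["eps_prime"].to_numpy(),
        temperature=float(meta.get("temperature_K", "nan")),
        sample_label=meta.get("sample", ""),
    )


def _truth_path(data_path: str | Path) -> Path:
    p = Path(data_path)
    return p.with_suffix(p.suffix + ".truth.json") if p.suffix != ".csv" else p.with_suffix(
        ".truth.json"
    )


def write_truth_sidecar(data_path: str | Path, truth: dict) -> Path:
    """Write the generator ground-truth JSON next to a data file."""
    path = _truth_path(data_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return path


def read_truth_sidecar(data_path: str | Path) -> dict:
    return json.loads(_truth_path(data_path).read_text())
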