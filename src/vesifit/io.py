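"""File I/O: delimited-text tables and YAML configuration.

CSV dialects:

* titration tables — columns ``lipid_molar, radius_nm, sd_nm, n``;
* diffusion profiles — columns ``position, intensity, position_index``;
* electropherograms — columns ``position_m, intensity, voltage_V,
  current_A, channel``.

YAML carries everything else: channel geometry, buffers, device
calibration, priors, and synthetic scenarios (shipped presets live in
``vesifit/scenarios``).  Concentrations in YAML are strings with explicit
units ("2 uM"); see :mod:`vesifit.units`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import PriorSpec
from .binding import BindingCurve, EquilibriumParams, TitrationPoint
from .errors import ConfigurationError
from .ffe import DeviceCalibration, Electropherogram
from .mds import ChannelGeometry, DiffusionProfile
from .physchem import BufferSpec, SolventProps
from .synthetic import ScenarioSpec
from .units import parse_concentration

# ---------------------------------------------------------------- titrations


def write_titration_csv(curve: BindingCurve, path) -> None:
    df = pd.DataFrame(
        {
            "lipid_molar": [p.lipid_total for p in curve.points],
            "radius_nm": [p.apparent_radius for p in curve.points],
            "sd_nm": [p.sd for p in curve.points],
            "n": [p.replicates for p in curve.points],
        }
    )
    df.to_csv(path, index=False)


def read_titration_csv(path, protein_total: float, r_free: float, r_bound: float,
                       condition: dict | None = None) -> BindingCurve:
    df = pd.read_csv(path)
    required = {"lipid_molar", "radius_nm"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"titration CSV needs columns {sorted(required)}")
    points = [
        TitrationPoint(
            lipid_total=float(row.lipid_molar),
            apparent_radius=float(row.radius_nm),
            sd=float(getattr(row, "sd_nm", 0.0) or 0.0),
            replicates=int(getattr(row, "n", 1) or 1),
        )
        for row in df.itertuples()
    ]
    return BindingCurve(
        points=tuple(points),
        protein_total=protein_total,
        r_free=r_free,
        r_bound=r_bound,
        condition=condition or {},
    )


# ------------------------------------------------------------------ profiles


def write_profiles_csv(profiles, path) -> None:
    frames = []
    for prof in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "position": prof.lateral_positions,
                    "intensity": prof.intensities,
                    "position_index": prof.position_index,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path, geometry: ChannelGeometry) -> list[DiffusionProfile]:
    df = pd.read_csv(path)
    required = {"position", "intensity", "position_index"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"profile CSV needs columns {sorted(required)}")
    out = []
    for idx, grp in df.groupby("position_index", sort=True):
        out.append(
            DiffusionProfile(
                lateral_positions=grp["position"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                residence_time=geometry.residence_time(int(idx)),
                position_index=int(idx),
            )
        )
    return out


# ----------------------------------------------------------- electropherograms


def write_electropherograms_csv(series, path) -> None:
    frames = []
    for eg in series:
        frames.append(
            pd.DataFrame(
                {
                    "position_m": eg.lateral_positions,
                    "intensity": eg.intensities,
                    "voltage_V": eg.applied_voltage,
                    "current_A": eg.measured_current,
                    "channel": eg.channel,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_electropherograms_csv(path) -> list[Electropherogram]:
    df = pd.read_csv(path)
    required = {"position_m", "intensity", "voltage_V", "current_A"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"electropherogram CSV needs columns {sorted(required)}")
    if "channel" not in df.columns:
        df["channel"] = "protein"
    out = []
    for (volt, chan), grp in df.groupby(["voltage_V", "channel"], sort=True):
        out.append(
            Electropherogram(
                lateral_positions=grp["position_m"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                applied_voltage=float(volt),
                measured_current=float(grp["current_A"].iloc[0]),
                channel=str(chan),
            )
        )
    return out


# ---------------------------------------------------------------------- YAML


def _load_yaml(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path_or_dict}: expected a YAML mapping")
    return data


def load_geometry(source) -> ChannelGeometry:
    """Channel geometry from YAML: lengths in μm/mm-free SI meters."""
    d = _load_yaml(source)
    kwargs = {}
    for key in ("width", "height", "sample_stream_fraction", "flow_rate"):
        if key in d:
            kwargs[key] = float(d[key])
    if "measurement_positions" in d:
        kwargs["measurement_positions"] = tuple(float(p) for p in d["measurement_positions"])
    return ChannelGeometry(**kwargs)


def load_buffer(source) -> BufferSpec:
    """Buffer from YAML: {phosphate_mM, pH, salts: [{name, mM, z}], temperature_C}."""
    d = _load_yaml(source)
    salts = tuple(
        (str(s["name"]), float(s["mM"]) * 1e-3, int(s["z"])) for s in d.get("salts", [])
    )
    return BufferSpec(
        phosphate_total=float(d.get("phosphate_mM", 0.0)) * 1e-3,
        pH=float(d.get("pH", 7.0)),
        added_salt=salts,
        temperature=float(d.get("temperature_C", 20.0)) + 273.15,
    )


def load_solvent(source) -> SolventProps:
    d = _load_yaml(source)
    kwargs = {}
    for key in ("viscosity", "relative_permittivity"):
        if key in d:
            kwargs[key] = float(d[key])
    if "temperature_C" in d:
        kwargs["temperature"] = float(d["temperature_C"]) + 273.15
    return SolventProps(**kwargs)


def load_calibration(source) -> DeviceCalibration:
    d = _load_yaml(source)
    kwargs = {
        k: float(d[k])
        for k in (
            "electrode_resistance", "chamber_width", "chamber_length",
            "chamber_height", "total_flow_rate",
        )
        if k in d
    }
    return DeviceCalibration(**kwargs)


def load_priors(source) -> PriorSpec:
    d = _load_yaml(source)
    kwargs = {}
    if "log10_kd_bounds" in d:
        kwargs["log10_kd_bounds"] = tuple(float(v) for v in d["log10_kd_bounds"])
    if "log10_a_bounds" in d:
        kwargs["log10_a_bounds"] = tuple(float(v) for v in d["log10_a_bounds"])
    if "sigma_max" in d:
        kwargs["sigma_max"] = float(d["sigma_max"])
    if "b" in d:
        b = d["b"]
        if isinstance(b, dict) and {"min", "max"} <= set(b):
            return PriorSpec.with_oligomer_b(int(b["min"]), int(b["max"]), **kwargs)
        if isinstance(b, dict):  # explicit empirical pmf {subunits: weight}
            kwargs["b_weights"] = {int(k): float(v) for k, v in b.items()}
        else:
            kwargs["b_weights"] = {int(b): 1.0}
    return PriorSpec(**kwargs)


def _parse_truth(d: dict) -> EquilibriumParams:
    kd = parse_concentration(d["kd"])
    if "lipids_per_site" in d:
        a = 1.0 / float(d["lipids_per_site"])
    else:
        a = float(d["a"])
    return EquilibriumParams(k_d=kd, a=a, b=int(d.get("b", 1)))


def load_scenario(source, seed: int | None = None) -> ScenarioSpec:
    """Load a synthetic-titration scenario from YAML (path, dict or preset name)."""
    if isinstance(source, str) and not Path(source).exists() and "/" not in source:
        return load_preset_scenario(source, seed=seed)
    d = _load_yaml(source)
    lip = d["lipid_concentrations"]
    if isinstance(lip, dict):
        lo = parse_concentration(lip["min"])
        hi = parse_concentration(lip["max"])
        n = int(lip.get("n", 12))
        if lip.get("spacing", "log") == "log":
            conc = tuple(np.geomspace(lo, hi, n))
        else:
            conc = tuple(np.linspace(lo, hi, n))
    else:
        conc = tuple(sorted(parse_concentration(c) for c in lip))
    noise = d.get("noise", {})
    spec_seed = seed if seed is not None else int(d.get("seed", 0))
    return ScenarioSpec(
        species=str(d["species"]),
        truth=_parse_truth(d["truth"]),
        protein_total=parse_concentration(d["protein_total"]),
        lipid_concentrations=conc,
        r_free=float(d["r_free_nm"]),
        r_bound=float(d["r_bound_nm"]),
        noise_sd=float(noise.get("sd", 0.0)),
        noise_mode=str(noise.get("mode", "radius")),
        replicates=int(d.get("replicates", 1)),
        seed=spec_seed,
        condition=dict(d.get("condition", {})),
    )


def list_preset_scenarios() -> list[str]:
    root = importlib.resources.files("vesifit") / "scenarios"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset_scenario(name: str, seed: int | None = None) -> ScenarioSpec:
    root = importlib.resources.files("vesifit") / "scenarios"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"no preset scenario {name!r}; available: {list_preset_scenarios()}"
        ) from None
    return load_scenario(yaml.safe_load(text), seed=seed)
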