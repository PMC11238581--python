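"""Synthetic data generation for every stage of the pipeline.

The generators produce titrations, competition measurements and
voltage-stepped electropherogram series from ground-truth parameters with
the noise structure the analysis assumes, so the whole pipeline can be
exercised and validated without instrument data.  All generators are pure
functions of (specification, seed).

Titration noise can be applied on the apparent-radius scale (what the
sizing instrument reports; the default) or on the fraction-bound scale
(matching the inference likelihood's assumption exactly); both are mapped
through the same mixture forward model that the analysis inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .binding import BindingCurve, EquilibriumParams, TitrationPoint, competitive_equilibrium, \
    equilibrium_fraction_bound
from .errors import InvalidInputError
from .ffe import DeviceCalibration, Electropherogram
from .mds import ChannelGeometry, MixtureModel
from .physchem import SolventProps

DEFAULT_GEOMETRY = ChannelGeometry()
DEFAULT_SOLVENT = SolventProps()


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth and design of one synthetic titration experiment."""

    species: Literal["monomer", "oligomer"]
    truth: EquilibriumParams
    protein_total: float  # M, monomer equivalents
    lipid_concentrations: tuple[float, ...]  # M, sorted ascending
    r_free: float  # nm
    r_bound: float  # nm
    noise_sd: float
    seed: int
    noise_mode: Literal["radius", "fraction"] = "radius"
    replicates: int = 1
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lip = tuple(float(c) for c in self.lipid_concentrations)
        if any(c < 0 for c in lip):
            raise InvalidInputError("lipid concentrations must be >= 0")
        if any(b < a for a, b in zip(lip, lip[1:])):
            raise InvalidInputError("lipid concentrations must be sorted ascending")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.r_free >= self.r_bound:
            raise InvalidInputError("r_free must be smaller than r_bound")
        object.__setattr__(self, "lipid_concentrations", lip)


@lru_cache(maxsize=32)
def _mixture_radius_interpolant(
    r_free: float,
    r_bound: float,
    geometry: ChannelGeometry,
    solvent: SolventProps,
    n_table: int = 41,
):
    """Monotone interpolant of apparent radius vs bound fraction.

    Tabulates the mixture forward model once per endpoint pair and returns
    a PCHIP interpolant; errors of the interpolation are far below the
    radius noise applied on top.
    """
    model = MixtureModel(r_free, r_bound, geometry, solvent)
    fracs, radii = model.radius_table(n=n_table)
    return PchipInterpolator(fracs, radii)


def fraction_to_apparent_radius(
    fraction_bound,
    r_free: float,
    r_bound: float,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    solvent: SolventProps = DEFAULT_SOLVENT,
):
    """Map true bound fraction(s) to the apparent radius the sizer reports."""
    interp = _mixture_radius_interpolant(r_free, r_bound, geometry, solvent)
    out = interp(np.clip(fraction_bound, 0.0, 1.0))
    return float(out) if np.isscalar(fraction_bound) else np.asarray(out)


def generate_titration(
    spec: ScenarioSpec,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    solvent: SolventProps = DEFAULT_SOLVENT,
) -> BindingCurve:
    """Synthesize a binding curve from ground truth.

    For each lipid concentration and replicate: equilibrium bound fraction
    → apparent radius through the mixture forward model → additive Gaussian
    noise (on the radius or the fraction, per ``spec.noise_mode``).  Each
    replicate becomes its own :class:`TitrationPoint`.  Reproducible given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    points: list[TitrationPoint] = []
    for lipid in spec.lipid_concentrations:
        f_true = equilibrium_fraction_bound(spec.truth, lipid, spec.protein_total)
        for _ in range(spec.replicates):
            if spec.noise_mode == "fraction":
                f_noisy = float(np.clip(f_true + rng.normal(0.0, spec.noise_sd), 0.0, 1.0)) \
                    if spec.noise_sd > 0 else f_true
                r_app = fraction_to_apparent_radius(
                    f_noisy, spec.r_free, spec.r_bound, geometry, solvent
                )
            else:
                r_app = fraction_to_apparent_radius(
                    f_true, spec.r_free, spec.r_bound, geometry, solvent
                )
                if spec.noise_sd > 0:
                    r_app += rng.normal(0.0, spec.noise_sd)
            points.append(
                TitrationPoint(
                    lipid_total=lipid,
                    apparent_radius=float(r_app),
                    sd=spec.noise_sd,
                    replicates=1,
                )
            )
    return BindingCurve(
        points=tuple(points),
        protein_total=spec.protein_total,
        r_free=spec.r_free,
        r_bound=spec.r_bound,
        condition={"species": spec.species, **spec.condition},
    )


def generate_competition_series(
    monomer: EquilibriumParams,
    oligomer: EquilibriumParams,
    monomer_total: float,
    oligomer_total: float,
    lipid_total: float,
    radii: dict[str, float],
    noise_sd: float,
    seed: int,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    solvent: SolventProps = DEFAULT_SOLVENT,
) -> dict[str, dict[str, float]]:
    """Synthesize the two-stage displacement experiment.

    Stage 1: monomer alone equilibrated with the lipid (single-species
    closed form); the oligomer channel reads its free radius.  Stage 2:
    oligomer added, both species re-equilibrate competitively.  Each
    stage's bound fractions are mapped to per-channel apparent radii with
    additive Gaussian radius noise.

    ``radii`` needs keys ``r_free_monomer``, ``r_bound_monomer``,
    ``r_free_oligomer``, ``r_bound_oligomer`` (nm).  Returns
    ``{"stage1": {...}, "stage2": {...}}`` with per-channel radii and the
    underlying true bound fractions.
    """
    required = {"r_free_monomer", "r_bound_monomer", "r_free_oligomer", "r_bound_oligomer"}
    if not required <= radii.keys():
        raise InvalidInputError(f"radii must contain {sorted(required)}")
    rng = np.random.default_rng(seed)

    f_m1 = equilibrium_fraction_bound(monomer, lipid_total, monomer_total)
    f_m2, f_o2 = competitive_equilibrium(
        monomer, oligomer, lipid_total, monomer_total, oligomer_total
    )

    def channel_radius(f: float, r_free: float, r_bound: float) -> float:
        r = fraction_to_apparent_radius(f, r_free, r_bound, geometry, solvent)
        return float(r + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))

    stage1 = {
        "monomer_radius": channel_radius(
            f_m1, radii["r_free_monomer"], radii["r_bound_monomer"]
        ),
        "oligomer_radius": channel_radius(
            0.0, radii["r_free_oligomer"], radii["r_bound_oligomer"]
        ),
        "f_monomer": float(f_m1),
        "f_oligomer": 0.0,
    }
    stage2 = {
        "monomer_radius": channel_radius(
            f_m2, radii["r_free_monomer"], radii["r_bound_monomer"]
        ),
        "oligomer_radius": channel_radius(
            f_o2, radii["r_free_oligomer"], radii["r_bound_oligomer"]
        ),
        "f_monomer": float(f_m2),
        "f_oligomer": float(f_o2),
    }
    return {"stage1": stage1, "stage2": stage2}


def generate_electropherogram_series(
    mobilities: Sequence[float],
    amplitudes: Sequence[float],
    voltages: Sequence[float],
    cal: DeviceCalibration,
    noise_sd: float,
    seed: int,
    chamber_resistance: float = 10e3,
    stream_width: float = 50e-6,
    n_x: int = 256,
    channel: str = "protein",
) -> list[Electropherogram]:
    """Synthesize a voltage-stepped μFFE series.

    Each species is a Gaussian stream injected at mid-width and displaced
    by ``μ·E·t_res`` at each voltage.  Currents follow the series-resistance
    device model ``I = V/(R_electrodes + R_chamber)``, so the effective
    field reconstructed by the analysis matches the one used here.
    ``noise_sd`` is additive intensity noise as a fraction of the peak.
    """
    if any(v < 0 for v in voltages):
        raise InvalidInputError("voltages must be >= 0")
    if len(mobilities) != len(amplitudes):
        raise InvalidInputError("mobilities and amplitudes must have equal length")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, cal.chamber_width, n_x)
    x0 = cal.chamber_width / 2.0
    t = cal.residence_time
    out = []
    for v in voltages:
        current = v / (cal.electrode_resistance + chamber_resistance)
        e_field = (v - current * cal.electrode_resistance) / cal.chamber_width
        y = np.zeros_like(x)
        for mu, amp in zip(mobilities, amplitudes):
            center = x0 + mu * e_field * t
            y += amp * np.exp(-0.5 * ((x - center) / stream_width) ** 2)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd * max(float(np.max(y)), 1e-30), size=y.shape)
        out.append(
            Electropherogram(
                lateral_positions=x,
                intensities=np.clip(y, 0.0, None),
                applied_voltage=float(v),
                measured_current=float(current),
                channel=channel,
            )
        )
    return out
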