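"""Microfluidic free-flow electrophoresis: mobility and ζ-potential analysis.

In a μFFE device the analyte stream flows through a shallow chamber while
an electric field is applied across it; charged species deflect laterally
in proportion to their electrophoretic mobility.  The analysis chain is:

1. ``effective_field`` — convert applied voltage and measured current to
   the field actually present in the chamber, correcting for the ohmic
   drop over the liquid electrodes (device calibration).
2. ``detect_peaks`` — locate species streams in a lateral fluorescence
   trace by fitting a small Gaussian mixture, component count chosen by BIC.
3. ``mobility_from_deflections`` — regress deflection velocity on field
   strength (least squares through the origin) to get the signed mobility.
4. ``zeta_from_mobility`` — invert an electrokinetic model (Smoluchowski,
   Hückel, or Henry with Ohshima's closure) for the ζ-potential, using the
   particle's hydrodynamic radius and the buffer's Debye length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths

from .errors import ConfigurationError, InvalidInputError, NumericalAccuracyError
from .physchem import EPS0, BufferSpec, SolventProps, debye_length, ionic_strength

ZetaModel = Literal["smoluchowski", "huckel", "henry"]


@dataclass(frozen=True)
class DeviceCalibration:
    """Electrical and geometric calibration of a μFFE device.

    ``electrode_resistance`` is the series resistance of the two liquid
    electrodes determined by filling the device with electrolyte and
    measuring current; the voltage actually dropped across the chamber is
    ``V − I·R``.  Flow defaults mirror typical operation (carrier + sample
    + electrolyte ≈ 1310 μL/h total).
    """

    electrode_resistance: float = 40e3  # ohm
    chamber_width: float = 2e-3  # m (deflection axis)
    chamber_length: float = 5e-3  # m (flow axis)
    chamber_height: float = 100e-6  # m
    total_flow_rate: float = 1310e-9 / 3600.0  # m³/s

    def __post_init__(self) -> None:
        for name in ("electrode_resistance", "chamber_width", "chamber_length",
                     "chamber_height", "total_flow_rate"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")

    @property
    def residence_time(self) -> float:
        """Plug-flow transit time (s) through the electrophoresis chamber."""
        area = self.chamber_width * self.chamber_height
        return self.chamber_length * area / self.total_flow_rate


@dataclass(frozen=True)
class Electropherogram:
    """Lateral fluorescence trace at one applied voltage."""

    lateral_positions: np.ndarray  # m
    intensities: np.ndarray  # a.u., >= 0
    applied_voltage: float  # V
    measured_current: float  # A
    channel: str = "protein"

    def __post_init__(self) -> None:
        x = np.asarray(self.lateral_positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise InvalidInputError("positions and intensities must be matching 1-D arrays")
        if np.any(np.diff(x) <= 0):
            raise InvalidInputError("positions must be strictly increasing")
        if self.applied_voltage < 0:
            raise InvalidInputError("applied voltage must be >= 0")
        object.__setattr__(self, "lateral_positions", x)
        object.__setattr__(self, "intensities", np.clip(y, 0.0, None))


@dataclass(frozen=True)
class MobilityResult:
    """Electrophoretic mobility of one species (signed; anionic < 0)."""

    mobility: float  # m² V⁻¹ s⁻¹
    stderr: float
    n_species: int = 1
    slopes: tuple[float, ...] = ()  # deflection-velocity slopes per species

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InvalidInputError("n_species must be >= 1")
        if self.stderr < 0:
            raise InvalidInputError("stderr must be >= 0")


@dataclass(frozen=True)
class ZetaResult:
    """ζ-potential with the electrokinetic model used to obtain it."""

    zeta_mv: float
    model: ZetaModel
    kappa_a: float = float("nan")


def effective_field(applied_voltage: float, measured_current: float,
                    cal: DeviceCalibration) -> float:
    """Field (V/m) in the chamber after subtracting the electrode ohmic drop.

    E = (V − I·R_electrodes) / chamber_width.
    """
    if applied_voltage < 0:
        raise InvalidInputError("applied voltage must be >= 0")
    drop = measured_current * cal.electrode_resistance
    if drop > applied_voltage * (1.0 + 1e-9):
        raise InvalidInputError(
            f"electrode drop {drop:.3g} V exceeds applied {applied_voltage:.3g} V; "
            "calibration inconsistent"
        )
    return max(applied_voltage - drop, 0.0) / cal.chamber_width


def _gaussian_mixture(x, *params):
    k = len(params) // 3
    y = np.zeros_like(x)
    for i in range(k):
        a, mu, sig = params[3 * i : 3 * i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def detect_peaks(eg: Electropherogram, max_species: int = 2) -> list[tuple[float, float, float]]:
    """Locate species streams as Gaussian components of the trace.

    Fits sums of 1..max_species Gaussians and keeps the component count
    with the lowest Bayesian information criterion.  Returns a list of
    ``(position, amplitude, width)`` sorted by position; components with
    amplitude below 3× the noise floor are dropped (a flat noise trace thus
    yields an empty list).
    """
    x = eg.lateral_positions
    y = eg.intensities
    if not np.any(y > 0):
        raise InvalidInputError("electropherogram has no signal")
    span = x[-1] - x[0]
    noise = float(np.median(np.abs(y - np.median(y)))) * 1.4826
    prominence = max(3.0 * noise, 0.05 * float(y.max()))
    idx, _ = find_peaks(y, prominence=prominence)
    if idx.size == 0:
        idx = np.array([int(np.argmax(y))])
    # initial widths from the measured half-maximum widths (fwhm/2.355)
    dx = span / (x.size - 1)
    fwhm = peak_widths(y, idx, rel_height=0.5)[0] * dx
    sig0 = np.maximum(fwhm / 2.355, 2.0 * dx)
    order = np.argsort(y[idx])[::-1]
    idx = idx[order]
    sig0 = sig0[order]

    best: tuple[float, list[float]] | None = None
    n = x.size
    for k in range(1, max_species + 1):
        p0 = []
        for i in range(k):
            if i < idx.size:
                j, s0 = idx[i], sig0[i]
            else:
                j, s0 = int(np.argmax(y)), span / 20.0
            p0 += [float(y[j]), float(x[j]), float(s0)]
        try:
            popt, _ = curve_fit(
                _gaussian_mixture, x, y, p0=p0,
                bounds=([0.0, x[0], span * 1e-4] * k, [np.inf, x[-1], span] * k),
                maxfev=20000,
            )
        except RuntimeError as err:
            if best is None and k == max_species:
                raise NumericalAccuracyError(f"peak fit failed to converge: {err}") from err
            continue
        rss = float(np.sum((y - _gaussian_mixture(x, *popt)) ** 2))
        bic = n * math.log(max(rss / n, 1e-300)) + 3 * k * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, list(popt))
    assert best is not None
    comps = [
        (best[1][3 * i + 1], best[1][3 * i], abs(best[1][3 * i + 2]))
        for i in range(len(best[1]) // 3)
    ]
    floor = 3.0 * noise
    comps = [c for c in comps if c[1] > floor] or comps[:1]
    return sorted(comps, key=lambda c: c[0])


def mobility_from_deflections(
    deflections: Sequence[tuple[float, float]],
    residence_time: float,
) -> MobilityResult:
    """Mobility from (field, lateral displacement) pairs for one species.

    Deflection velocity is ``v = displacement / residence_time``; the
    mobility is the least-squares slope of v against E through the origin
    (zero field must give zero deflection).  The sign of the displacement
    convention is preserved: anode-ward deflection of an anionic species
    yields a negative mobility.
    """
    if residence_time <= 0:
        raise InvalidInputError("residence time must be > 0")
    arr = np.asarray(deflections, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidInputError("need >= 2 (field, displacement) pairs")
    e, d = arr[:, 0], arr[:, 1]
    if np.allclose(e, e[0]):
        raise InvalidInputError("all field values identical; regression singular")
    v = d / residence_time
    sxx = float(np.sum(e * e))
    slope = float(np.sum(e * v)) / sxx
    resid = v - slope * e
    dof = max(e.size - 1, 1)
    stderr = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    return MobilityResult(mobility=slope, stderr=stderr, n_species=1, slopes=(slope,))


def mobilities_from_series(
    series: Sequence[Electropherogram],
    cal: DeviceCalibration,
    max_species: int = 1,
) -> list[MobilityResult]:
    """Track species across a voltage-stepped series and fit their mobilities.

    Peaks are detected at every voltage and matched across voltages by
    positional order (deflections are monotone in field, so ordering is
    preserved for non-crossing species).  Displacements are referenced to
    each species' zero-voltage stream position.
    """
    if len(series) < 2:
        raise InvalidInputError("need electropherograms at >= 2 voltages")
    egs = sorted(series, key=lambda e: e.applied_voltage)
    if egs[0].applied_voltage != 0:
        raise InvalidInputError("series must include a 0 V reference trace")
    peak_sets = [detect_peaks(eg, max_species=max_species) for eg in egs]
    # All species start at the injection position; at 0 V they overlap, so
    # the reference is the (possibly merged) 0 V stream position.
    ref_x = float(np.mean([p[0] for p in peak_sets[0]]))
    # The species count is best resolved at the highest field.
    n_species = len(peak_sets[-1])
    t = cal.residence_time
    results = []
    for s in range(n_species):
        pairs = [(0.0, 0.0)]
        for eg, peaks in zip(egs[1:], peak_sets[1:]):
            if len(peaks) != n_species:
                continue  # species unresolved (merged streams) at this voltage
            e_field = effective_field(eg.applied_voltage, eg.measured_current, cal)
            # sorted-by-position index s tracks one species: deflection is
            # linear in field, so non-crossing streams keep their order.
            pairs.append((e_field, peaks[s][0] - ref_x))
        res = mobility_from_deflections(pairs, t)
        results.append(
            MobilityResult(res.mobility, res.stderr, n_species=n_species, slopes=res.slopes)
        )
    return results


def henry_factor(kappa_a: float) -> float:
    """Henry's function f(κa) via Ohshima's approximation.

    f(κa) = 1 + ½·[1 + 2.5/(κa·(1 + 2·e^{−κa}))]⁻³; monotone increasing
    from the Hückel limit f(0⁺)=1 to the Smoluchowski limit f(∞)=1.5.
    """
    if kappa_a <= 0:
        raise InvalidInputError("kappa_a must be > 0")
    denom = 1.0 + 2.5 / (kappa_a * (1.0 + 2.0 * math.exp(-kappa_a)))
    return 1.0 + 0.5 / denom**3


def zeta_from_mobility(
    mob: MobilityResult | float,
    r_h_nm: float,
    buffer: BufferSpec,
    solvent: SolventProps,
    model: ZetaModel = "henry",
) -> ZetaResult:
    """ζ-potential (mV) from electrophoretic mobility and particle size.

    Henry: μ = 2·ε·ε₀·ζ·f(κ·r_h) / (3η); Hückel is the f≡1 special case and
    Smoluchowski is μ = ε·ε₀·ζ/η.  The sign of ζ equals the sign of μ.
    """
    mu = mob.mobility if isinstance(mob, MobilityResult) else float(mob)
    if r_h_nm <= 0:
        raise InvalidInputError("hydrodynamic radius must be > 0")
    eps = solvent.relative_permittivity * EPS0
    eta = solvent.viscosity
    if model == "smoluchowski":
        zeta = mu * eta / eps
        return ZetaResult(zeta_mv=zeta * 1e3, model=model)
    if model in ("huckel", "henry"):
        i_molar = ionic_strength(buffer)
        kappa_a = (r_h_nm * 1e-9) / debye_length(i_molar, solvent)
        f = 1.0 if model == "huckel" else henry_factor(kappa_a)
        zeta = 3.0 * mu * eta / (2.0 * eps * f)
        return ZetaResult(zeta_mv=zeta * 1e3, model=model, kappa_a=kappa_a)
    raise ConfigurationError(f"unknown electrokinetic model {model!r}")


def mobility_from_zeta(
    zeta_mv: float,
    r_h_nm: float,
    buffer: BufferSpec,
    solvent: SolventProps,
    model: ZetaModel = "henry",
) -> float:
    """Forward electrokinetic model: mobility (m²V⁻¹s⁻¹) from ζ (mV)."""
    zeta = zeta_mv * 1e-3
    eps = solvent.relative_permittivity * EPS0
    eta = solvent.viscosity
    if model == "smoluchowski":
        return zeta * eps / eta
    if model in ("huckel", "henry"):
        kappa_a = (r_h_nm * 1e-9) / debye_length(ionic_strength(buffer), solvent)
        f = 1.0 if model == "huckel" else henry_factor(kappa_a)
        return 2.0 * eps * zeta * f / (3.0 * eta)
    raise ConfigurationError(f"unknown electrokinetic model {model!r}")
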