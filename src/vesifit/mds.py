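"""Microfluidic diffusional sizing: forward profiles and radius inversion.

In a diffusional-sizing chip an analyte stream is co-flowed next to buffer
under laminar flow; the only lateral transport is diffusion, so the shape
of the lateral fluorescence profile at a known residence time encodes the
analyte's diffusion coefficient and hence (via Stokes–Einstein) its
hydrodynamic radius.

The forward model here is 1-D diffusion across the channel width with
reflecting (no-flux) walls and a top-hat initial condition occupying a
fraction of the width on one side.  Axial transport is treated as plug
flow: the profile recorded a distance ``L`` downstream corresponds to the
diffusion solution at residence time ``t = L·(width·height)/flow_rate``.
The solution is the cosine eigenfunction series

    c(x, τ) = w₀ + 2 Σ_{n≥1} sin(nπw₀)/(nπ) · cos(nπx) · exp(−(nπ)²τ)

with x the lateral coordinate normalized to [0, 1], w₀ the sample-stream
fraction and τ = D·t/width² the dimensionless time.

Radius inversion fits observed (area-normalized) profiles against a basis
of simulated single-species profiles on a log-spaced radius grid, with
quadratic interpolation of the residual around the grid minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, NumericalAccuracyError
from .physchem import SolventProps, stokes_einstein_diffusivity

#: Series truncation: add terms until the next term's amplitude bound drops
#: below this value, but never fewer than SERIES_MIN_TERMS.
SERIES_TOL = 1e-10
SERIES_MIN_TERMS = 64
SERIES_MAX_TERMS = 200_000


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry and operating point of the sizing channel.

    ``measurement_positions`` are downstream distances (m) at which lateral
    profiles are imaged.  The default geometry is a configurable stand-in
    with dimensions typical of PDMS sizing chips.
    """

    width: float = 300e-6  # m, lateral diffusion axis
    height: float = 50e-6  # m
    sample_stream_fraction: float = 0.25
    flow_rate: float = 100e-9 / 3600.0  # m³/s (100 μL/h)
    measurement_positions: tuple[float, ...] = (5e-3, 20e-3, 50e-3, 100e-3)

    def __post_init__(self) -> None:
        if not (0.0 < self.sample_stream_fraction < 1.0):
            raise InvalidInputError("sample_stream_fraction must lie in (0, 1)")
        if self.width <= 0 or self.height <= 0:
            raise InvalidInputError("channel width and height must be > 0")
        if self.flow_rate <= 0:
            raise InvalidInputError("flow_rate must be > 0")
        pos = self.measurement_positions
        if len(pos) == 0 or any(p <= 0 for p in pos):
            raise InvalidInputError("measurement positions must be positive")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InvalidInputError("measurement positions must be strictly increasing")

    def residence_time(self, position_index: int) -> float:
        """Plug-flow residence time (s) at the indexed measurement position."""
        pos = self.measurement_positions[position_index]
        return pos * self.width * self.height / self.flow_rate


@dataclass(frozen=True)
class DiffusionProfile:
    """A lateral intensity trace at one measurement position.

    ``lateral_positions`` are normalized to [0, 1] across the channel width;
    intensities are arbitrary units, area-normalized on construction so the
    trapezoidal integral is 1.  Background-subtracted measurement noise can
    dip slightly below zero; such values are kept as-is (clipping them would
    bias the area normalization and hence the fitted radius), but traces
    with gross negative excursions (beyond 20% of the peak) are rejected.
    """

    lateral_positions: np.ndarray
    intensities: np.ndarray
    residence_time: float
    position_index: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.lateral_positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise InvalidInputError("positions and intensities must be matching 1-D arrays")
        if np.any(np.diff(x) <= 0):
            raise InvalidInputError("lateral positions must be strictly increasing")
        peak = float(np.max(y)) if y.size else 0.0
        if peak <= 0:
            raise InvalidInputError("profile has no positive intensity")
        if np.any(y < -0.2 * peak):
            raise InvalidInputError("intensities grossly negative; not a valid trace")
        area = np.trapezoid(y, x)
        if area <= 0:
            raise InvalidInputError("profile has zero integrated intensity")
        object.__setattr__(self, "lateral_positions", x)
        object.__setattr__(self, "intensities", y / area)


@dataclass(frozen=True)
class SizingResult:
    """Outcome of a radius fit."""

    r_h: float  # nm
    residual: float
    basis_bounds: tuple[float, float]  # nm
    at_boundary: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.basis_bounds
        if not (lo <= self.r_h <= hi):
            raise InvalidInputError("fitted radius outside basis bounds")
        if self.residual < 0:
            raise InvalidInputError("residual must be >= 0")


def _series_profile(x: np.ndarray, w0: float, tau: float) -> np.ndarray:
    """Evaluate the reflecting-wall diffusion series at dimensionless time tau.

    Returns the concentration normalized so that its integral over [0, 1] is 1.
    """
    if tau < 0:
        raise InvalidInputError("residence time must be >= 0")
    if tau == 0.0:
        # Exact initial condition: top-hat of width w0 at the x=0 wall.
        c = np.where(x < w0, 1.0, 0.0)
        c[np.isclose(x, w0)] = 0.5
        return c / w0
    # Number of terms needed: amplitude bound 2/(nπ)·exp(−(nπ)²τ) < tol.
    n_needed = SERIES_MIN_TERMS
    if tau > 0:
        # exp(−(nπ)²τ) < tol  ⇔  n > sqrt(−ln tol / τ)/π
        n_decay = math.sqrt(max(-math.log(SERIES_TOL), 1.0) / tau) / math.pi
        n_needed = max(SERIES_MIN_TERMS, int(n_decay) + 2)
    if n_needed > SERIES_MAX_TERMS:
        raise NumericalAccuracyError(
            f"series needs {n_needed} terms (> {SERIES_MAX_TERMS}); "
            "residence time too small for the configured accuracy"
        )
    n = np.arange(1, n_needed + 1)
    npi = n * math.pi
    amp = 2.0 * np.sin(npi * w0) / npi * np.exp(-(npi**2) * tau)
    c = w0 + np.cos(np.outer(x, npi)) @ amp
    return np.clip(c, 0.0, None) / w0


def simulate_profile(
    r_h_nm: float,
    geometry: ChannelGeometry,
    solvent: SolventProps,
    position_index: int,
    n_x: int = 201,
) -> DiffusionProfile:
    """Simulate the lateral diffusion profile for a species of radius ``r_h_nm``.

    The profile is evaluated on ``n_x`` evenly spaced normalized lateral
    positions and area-normalized.
    """
    if r_h_nm <= 0:
        raise InvalidInputError(f"radius must be > 0, got {r_h_nm}")
    if not (0 <= position_index < len(geometry.measurement_positions)):
        raise InvalidInputError(f"position index {position_index} out of range")
    d = stokes_einstein_diffusivity(r_h_nm * 1e-9, solvent)
    t = geometry.residence_time(position_index)
    tau = d * t / geometry.width**2
    x = np.linspace(0.0, 1.0, n_x)
    c = _series_profile(x, geometry.sample_stream_fraction, tau)
    return DiffusionProfile(x, c, residence_time=t, position_index=position_index)


class RadiusFitter:
    """Least-squares radius inversion against a precomputed profile basis.

    The basis holds simulated profiles for ``n_basis`` log-spaced radii
    between ``basis_bounds`` (nm) at every measurement position of the
    geometry.  Building the basis dominates the cost, so one fitter should
    be reused across many fits with the same geometry/solvent.
    """

    def __init__(
        self,
        geometry: ChannelGeometry,
        solvent: SolventProps,
        basis_bounds: tuple[float, float] = (0.5, 300.0),
        n_basis: int = 60,
        n_x: int = 201,
    ) -> None:
        lo, hi = basis_bounds
        if not (0 < lo < hi):
            raise InvalidInputError("basis bounds must satisfy 0 < min < max")
        self.geometry = geometry
        self.solvent = solvent
        self.basis_bounds = (float(lo), float(hi))
        self.radii = np.geomspace(lo, hi, n_basis)
        self.x = np.linspace(0.0, 1.0, n_x)
        self.n_positions = len(geometry.measurement_positions)
        # basis[j, p, :] = area-normalized profile of radius j at position p
        self.basis = np.empty((n_basis, self.n_positions, n_x))
        for j, r in enumerate(self.radii):
            for p in range(self.n_positions):
                prof = simulate_profile(r, geometry, solvent, p, n_x=n_x)
                self.basis[j, p] = prof.intensities

    def basis_profile(self, radius_index: int, position_index: int) -> np.ndarray:
        return self.basis[radius_index, position_index]

    def _observed_matrix(self, profiles: Sequence[DiffusionProfile]) -> tuple[np.ndarray, list[int]]:
        obs = np.empty((len(profiles), self.x.size))
        idx = []
        for i, prof in enumerate(profiles):
            if np.allclose(prof.intensities, prof.intensities[0]) and prof.intensities[0] == 0:
                raise InvalidInputError("all-zero profile")
            y = prof.intensities
            if prof.lateral_positions.shape != self.x.shape or not np.allclose(
                prof.lateral_positions, self.x
            ):
                y = np.interp(self.x, prof.lateral_positions, y)
            obs[i] = y
            idx.append(prof.position_index)
        return obs, idx

    def fit(self, profiles: Sequence[DiffusionProfile]) -> SizingResult:
        """Fit a single hydrodynamic radius to one or more observed profiles.

        The residual is the summed squared difference between observed and
        basis profiles at the matching measurement positions; the minimizing
        radius is refined by quadratic interpolation in log-radius around
        the grid minimum.  A minimum on the grid boundary is returned with
        ``at_boundary=True``.
        """
        if len(profiles) == 0:
            raise InvalidInputError("need at least one profile")
        obs, pos_idx = self._observed_matrix(profiles)
        sse = np.zeros(self.radii.size)
        for i, p in enumerate(pos_idx):
            diff = self.basis[:, p, :] - obs[i][None, :]
            sse += np.sum(diff * diff, axis=1)
        j = int(np.argmin(sse))
        if j == 0 or j == self.radii.size - 1:
            return SizingResult(
                r_h=float(self.radii[j]),
                residual=float(sse[j]),
                basis_bounds=self.basis_bounds,
                at_boundary=True,
            )
        # Parabola through the three bracketing points in log-radius.
        lr = np.log(self.radii[j - 1 : j + 2])
        s = sse[j - 1 : j + 2]
        denom = (s[0] - 2.0 * s[1] + s[2])
        if denom <= 0:
            lr_min = lr[1]
        else:
            lr_min = lr[1] + 0.5 * (lr[0] - lr[1]) * (s[2] - s[0]) / denom * (
                (lr[2] - lr[1]) / (lr[1] - lr[0])
            )
            lr_min = float(np.clip(lr_min, lr[0], lr[2]))
        return SizingResult(
            r_h=float(math.exp(lr_min)),
            residual=float(s[1]),
            basis_bounds=self.basis_bounds,
        )


@lru_cache(maxsize=8)
def _cached_fitter(
    geometry: ChannelGeometry,
    solvent: SolventProps,
    basis_bounds: tuple[float, float],
    n_basis: int,
    n_x: int,
) -> RadiusFitter:
    return RadiusFitter(geometry, solvent, basis_bounds, n_basis=n_basis, n_x=n_x)


def get_fitter(
    geometry: ChannelGeometry,
    solvent: SolventProps,
    basis_bounds: tuple[float, float] = (0.5, 300.0),
    n_basis: int = 60,
    n_x: int = 201,
) -> RadiusFitter:
    """Return a (cached) :class:`RadiusFitter` for the given configuration."""
    return _cached_fitter(geometry, solvent, tuple(basis_bounds), n_basis, n_x)


def fit_radius(
    profiles: Sequence[DiffusionProfile],
    geometry: ChannelGeometry,
    solvent: SolventProps,
    basis_bounds: tuple[float, float] = (0.5, 300.0),
) -> SizingResult:
    """Convenience wrapper: fit profiles with a cached basis fitter."""
    return get_fitter(geometry, solvent, basis_bounds).fit(profiles)


class MixtureModel:
    """Forward model of the apparent radius of a free/bound mixture.

    Precomputes the endpoint profiles once so that the apparent radius can
    be evaluated cheaply for many bound fractions (calibration anchors,
    synthetic titrations).
    """

    def __init__(
        self,
        r_free_nm: float,
        r_bound_nm: float,
        geometry: ChannelGeometry,
        solvent: SolventProps,
        fitter: RadiusFitter | None = None,
    ) -> None:
        if r_free_nm >= r_bound_nm:
            raise InvalidInputError("r_free must be smaller than r_bound")
        self.r_free_nm = float(r_free_nm)
        self.r_bound_nm = float(r_bound_nm)
        self.fitter = fitter if fitter is not None else get_fitter(geometry, solvent)
        self.geometry = geometry
        self.solvent = solvent
        nx = self.fitter.x.size
        self._free = [
            simulate_profile(r_free_nm, geometry, solvent, p, n_x=nx)
            for p in range(self.fitter.n_positions)
        ]
        self._bound = [
            simulate_profile(r_bound_nm, geometry, solvent, p, n_x=nx)
            for p in range(self.fitter.n_positions)
        ]

    def apparent_radius(self, fraction_bound: float) -> float:
        """Apparent radius (nm) reported by the fit for a given bound fraction."""
        f = float(fraction_bound)
        if not (0.0 <= f <= 1.0):
            raise InvalidInputError("fraction_bound must lie in [0, 1]")
        profiles = []
        for p in range(self.fitter.n_positions):
            mix = f * self._bound[p].intensities + (1.0 - f) * self._free[p].intensities
            profiles.append(
                DiffusionProfile(
                    self.fitter.x,
                    mix,
                    residence_time=self._free[p].residence_time,
                    position_index=p,
                )
            )
        return self.fitter.fit(profiles).r_h

    def radius_table(self, n: int = 41) -> tuple[np.ndarray, np.ndarray]:
        """Tabulate (fractions, apparent radii) on an even grid of n fractions."""
        fracs = np.linspace(0.0, 1.0, n)
        radii = np.array([self.apparent_radius(f) for f in fracs])
        return fracs, radii


def apparent_radius_of_mixture(
    fraction_bound: float,
    r_free_nm: float,
    r_bound_nm: float,
    geometry: ChannelGeometry,
    solvent: SolventProps,
    fitter: RadiusFitter | None = None,
) -> float:
    """Apparent single-species radius of a free/bound two-component mixture.

    Builds the intensity-weighted combination
    ``f·profile(r_bound) + (1−f)·profile(r_free)`` at every measurement
    position and fits a single radius to it.  This is the forward model of
    what the sizing instrument reports for a partially bound sample; it is
    monotone non-decreasing in ``fraction_bound`` but not linear.
    """
    if not (0.0 <= fraction_bound <= 1.0):
        raise InvalidInputError("fraction_bound must lie in [0, 1]")
    if r_free_nm >= r_bound_nm:
        raise InvalidInputError("r_free must be smaller than r_bound")
    if fitter is None:
        fitter = get_fitter(geometry, solvent)
    profiles = []
    for p in range(fitter.n_positions):
        free = simulate_profile(r_free_nm, geometry, solvent, p, n_x=fitter.x.size)
        bound = simulate_profile(r_bound_nm, geometry, solvent, p, n_x=fitter.x.size)
        mix = fraction_bound * bound.intensities + (1.0 - fraction_bound) * free.intensities
        profiles.append(
            DiffusionProfile(fitter.x, mix, residence_time=free.residence_time, position_index=p)
        )
    return fitter.fit(profiles).r_h
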