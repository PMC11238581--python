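"""Two-state protein–vesicle binding: conversions and equilibrium closed forms.

The binding model treats a protein "particle" (a monomer, or an oligomer of
``b`` monomer subunits) binding a site on the vesicle surface, with sites
proportional to the total lipid concentration: the effective number of
particles bound per lipid is ``a``, so the molar site concentration is
``S₀ = a·[A]₀`` and ``1/a`` is the number of lipids per binding site.
The particle concentration is ``P₀ = [B]₀/b`` where ``[B]₀`` is the total
protein in monomer equivalents.  With dissociation constant ``K_d``
(molar particle–site interactions) and no cooperativity the bound-particle
concentration is the physical root of the 1:1 mass-action quadratic.

The module also provides the two ways apparent hydrodynamic radii are
converted to bound fractions — exact linear interpolation between the free
and fully bound radii (adequate when the radius contrast is small, as for
oligomers) and a polynomial calibration built from the mixture forward
model (needed for monomers, whose free/bound radius contrast is large) —
plus a two-species competitive extension of the equilibrium used to
interpret displacement experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, InvalidInputError
from .mds import ChannelGeometry, MixtureModel, RadiusFitter
from .physchem import SolventProps


@dataclass(frozen=True)
class EquilibriumParams:
    """(K_d, a, b) for one binding species.

    k_d: molar dissociation constant of the particle–site interaction.
    a: effective particles bound per lipid molecule (1/a = lipids per site).
    b: monomer subunits per particle (1 for monomeric protein).
    """

    k_d: float
    a: float
    b: int = 1

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise InvalidInputError("k_d must be > 0")
        if self.a <= 0:
            raise InvalidInputError("a must be > 0")
        if self.b < 1 or int(self.b) != self.b:
            raise InvalidInputError("b must be an integer >= 1")

    @property
    def lipids_per_site(self) -> float:
        return 1.0 / self.a


@dataclass(frozen=True)
class TitrationPoint:
    """One titration measurement: apparent radius at a total lipid concentration."""

    lipid_total: float  # M
    apparent_radius: float  # nm
    sd: float = 0.0  # nm
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.lipid_total < 0:
            raise InvalidInputError("lipid_total must be >= 0")
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


@dataclass(frozen=True)
class BindingCurve:
    """A titration of apparent radius vs lipid concentration at fixed protein.

    ``protein_total`` is in molar monomer equivalents.  ``r_free`` and
    ``r_bound`` are the endpoint radii used for fraction-bound conversion.
    ``condition`` carries free-form metadata (pH, buffer, vesicle class).
    """

    points: tuple[TitrationPoint, ...]
    protein_total: float  # M, monomer equivalents
    r_free: float  # nm
    r_bound: float  # nm
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.points) < 4:
            raise InvalidInputError("a binding curve needs at least 4 points")
        if self.r_free >= self.r_bound:
            raise InvalidInputError("r_free must be smaller than r_bound")
        if self.protein_total <= 0:
            raise InvalidInputError("protein_total must be > 0")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def lipid_totals(self) -> np.ndarray:
        return np.array([p.lipid_total for p in self.points])

    @property
    def apparent_radii(self) -> np.ndarray:
        return np.array([p.apparent_radius for p in self.points])


def fraction_bound_linear(r_h, r_free: float, r_bound: float):
    """Linear radius→fraction conversion, clamped to [0, 1].

    f = (r_h − r_free)/(r_bound − r_free).  Adequate when the fold change
    between free and bound radii is small; measurement noise can place radii
    outside the endpoints, hence the clamp.
    """
    if r_free >= r_bound:
        raise InvalidInputError("r_free must be smaller than r_bound")
    f = (np.asarray(r_h, dtype=float) - r_free) / (r_bound - r_free)
    out = np.clip(f, 0.0, 1.0)
    return float(out) if np.isscalar(r_h) else out


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map apparent radius (nm) → fraction bound.

    Built from anchor pairs (true fraction, apparent radius of the
    corresponding free/bound profile mixture) computed with the sizing
    forward model.  Inversion uses a shape-preserving monotone (PCHIP)
    interpolant through the anchors, which closes the forward–inverse loop
    essentially exactly; ``coefficients`` additionally store a least-squares
    second-order polynomial fraction ≈ c0 + c1·r + c2·r² as a descriptive
    approximation (the apparent radius is strongly super-linear in the bound
    fraction, so the quadratic alone can carry bias of several percent for
    large free→bound contrasts).  Outputs are clamped to [0, 1];
    ``valid_range`` is (r_free, r_bound).
    """

    anchor_fractions: tuple[float, ...]
    anchor_radii: tuple[float, ...]
    coefficients: tuple[float, float, float]
    valid_range: tuple[float, float]

    def _interpolant(self):
        from scipy.interpolate import PchipInterpolator

        return PchipInterpolator(np.array(self.anchor_radii), np.array(self.anchor_fractions))

    def fraction_bound(self, r_h):
        r = np.clip(np.asarray(r_h, dtype=float), *self.valid_range)
        out = np.clip(self._interpolant()(r), 0.0, 1.0)
        return float(out) if np.isscalar(r_h) else out

    def fraction_bound_quadratic(self, r_h):
        """Fraction from the descriptive quadratic approximation (may be biased)."""
        c0, c1, c2 = self.coefficients
        r = np.asarray(r_h, dtype=float)
        out = np.clip(c0 + c1 * r + c2 * r * r, 0.0, 1.0)
        return float(out) if np.isscalar(r_h) else out


def build_calibration(
    r_free: float,
    r_bound: float,
    geometry: ChannelGeometry,
    solvent: SolventProps,
    n_anchor: int = 21,
    fitter: RadiusFitter | None = None,
) -> CalibrationCurve:
    """Build a radius→fraction calibration from the mixture forward model.

    Computes the apparent radius of free/bound profile mixtures at
    ``n_anchor`` evenly spaced true bound fractions and constructs the
    monotone inverse map (plus a least-squares quadratic summary).  Raises
    :class:`CalibrationError` if the anchors are non-monotone (radius
    contrast too small to calibrate) or the endpoint contract fails.
    """
    if n_anchor < 5:
        raise InvalidInputError("need at least 5 calibration anchors")
    model = MixtureModel(r_free, r_bound, geometry, solvent, fitter=fitter)
    fracs, radii = model.radius_table(n=n_anchor)
    if np.any(np.diff(radii) <= 0):
        raise CalibrationError(
            "apparent-radius anchors are not strictly increasing; "
            "radius contrast too small for a usable calibration"
        )
    design = np.vander(radii, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(design, fracs, rcond=None)
    cal = CalibrationCurve(
        anchor_fractions=tuple(float(f) for f in fracs),
        anchor_radii=tuple(float(r) for r in radii),
        coefficients=tuple(float(c) for c in coef),
        valid_range=(float(radii[0]), float(radii[-1])),
    )
    if abs(cal.fraction_bound(radii[0])) > 1e-3 or abs(cal.fraction_bound(radii[-1]) - 1.0) > 1e-3:
        raise CalibrationError("calibration does not map endpoints to 0/1 within 1e-3")
    return cal


def equilibrium_fraction_bound(params: EquilibriumParams, lipid_total, protein_total):
    """Fraction of protein bound at equilibrium under the two-state model.

    With P₀ = [B]₀/b particles and S₀ = a·[A]₀ sites, the bound-complex
    concentration is the physical root of the 1:1 mass-action quadratic,
    evaluated in the cancellation-safe form

        [PS] = 2·P₀·S₀ / (P₀ + S₀ + K_d + sqrt((P₀ + S₀ + K_d)² − 4·P₀·S₀))

    and the returned fraction is [PS]/P₀ (equal for particles and monomer
    equivalents, since every particle carries b monomers).  Vectorized over
    ``lipid_total``.
    """
    a0 = np.asarray(lipid_total, dtype=float)
    if np.any(a0 < 0) or np.any(np.asarray(protein_total) < 0):
        raise InvalidInputError("concentrations must be >= 0")
    p0 = protein_total / params.b
    s0 = params.a * a0
    s = p0 + s0 + params.k_d
    disc = np.sqrt(np.maximum(s * s - 4.0 * p0 * s0, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = 2.0 * p0 * s0 / (s + disc)
        f = np.where(p0 > 0, ps / np.where(p0 > 0, p0, 1.0), 0.0)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if np.isscalar(lipid_total) else f


def competitive_equilibrium(
    monomer: EquilibriumParams,
    oligomer: EquilibriumParams,
    lipid_total: float,
    monomer_total: float,
    oligomer_total: float,
) -> tuple[float, float]:
    """Bound fractions of two species competing for the same lipid surface.

    Both species draw sites from a shared lipid pool: a bound particle of
    species i occupies 1/a_i lipids, and the free-site concentration seen by
    species i is a_i·[A]_free.  Mass action per species plus lipid
    conservation gives a single monotone equation in the free lipid
    concentration, solved by bracketing root finding:

        [A]_free + bound_m/a_m + bound_o/a_o = [A]₀,
        bound_i = P₀ᵢ · a_i·[A]_free / (K_dᵢ + a_i·[A]_free).

    Totals are monomer equivalents; returns (f_bound_monomer,
    f_bound_oligomer), each the bound fraction of that species (0 when the
    species is absent).  Reduces exactly to the single-species closed form
    when the other species' total is zero.
    """
    if lipid_total < 0 or monomer_total < 0 or oligomer_total < 0:
        raise InvalidInputError("concentrations must be >= 0")
    p_m = monomer_total / monomer.b
    p_o = oligomer_total / oligomer.b

    if lipid_total == 0.0:
        return 0.0, 0.0

    def bound(params: EquilibriumParams, p0: float, a_free: float) -> float:
        s_free = params.a * a_free
        return p0 * s_free / (params.k_d + s_free)

    def excess(a_free: float) -> float:
        used = (
            bound(monomer, p_m, a_free) / monomer.a
            + bound(oligomer, p_o, a_free) / oligomer.a
        )
        return a_free + used - lipid_total

    # excess is strictly increasing, negative at 0 and >= 0 at lipid_total.
    a_free = brentq(excess, 0.0, lipid_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    f_m = bound(monomer, p_m, a_free) / p_m if p_m > 0 else 0.0
    f_o = bound(oligomer, p_o, a_free) / p_o if p_o > 0 else 0.0
    return float(np.clip(f_m, 0.0, 1.0)), float(np.clip(f_o, 0.0, 1.0))
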