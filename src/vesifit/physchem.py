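"""Shared physical-chemistry primitives.

Constants, solvent and buffer descriptions, Stokes–Einstein conversion
between hydrodynamic radius and diffusion coefficient, phosphate-buffer
ionic strength, and the Debye screening length.  Everything downstream
(diffusional sizing, electrokinetics) builds on these.

Units are strict SI internally: meters, seconds, kelvin, Pa·s, volts,
molar (mol/L) for solution concentrations where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import constants as _const

from .errors import InvalidInputError

#: Boltzmann constant, J/K
K_B = _const.k
#: Avogadro constant, 1/mol
N_A = _const.N_A
#: Elementary charge, C
E_CHARGE = _const.e
#: Vacuum permittivity, F/m
EPS0 = _const.epsilon_0

#: Phosphoric acid pK_a values at 25 °C (H3PO4 / H2PO4- / HPO4^2-).
#: No ionic-strength correction is applied; see the methods note.
PHOSPHATE_PKAS = (2.15, 7.21, 12.33)


@dataclass(frozen=True)
class SolventProps:
    """Bulk solvent properties used by Stokes–Einstein and electrokinetics.

    Defaults are water at 20 °C.
    """

    viscosity: float = 1.002e-3  # Pa·s
    relative_permittivity: float = 80.1
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise InvalidInputError(f"viscosity must be > 0, got {self.viscosity}")
        if self.relative_permittivity <= 1:
            raise InvalidInputError(
                f"relative permittivity must be > 1, got {self.relative_permittivity}"
            )
        if self.temperature <= 0:
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")


@dataclass(frozen=True)
class BufferSpec:
    """A sodium phosphate buffer, optionally with extra fully dissociated salts.

    ``phosphate_total`` is the total molar phosphate concentration (all
    protonation states); the pH fixes the speciation and the Na+ counter-ion
    concentration follows from electroneutrality.  ``added_salt`` lists extra
    ionic species explicitly as ``(name, molar_concentration, integer_charge)``
    tuples — e.g. 0.1 M NaCl is two entries.
    """

    phosphate_total: float = 0.020  # M
    pH: float = 6.5
    added_salt: tuple[tuple[str, float, int], ...] = field(default_factory=tuple)
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        if self.phosphate_total < 0:
            raise InvalidInputError("phosphate_total must be >= 0")
        if not (0.0 < self.pH < 14.0):
            raise InvalidInputError(f"pH must lie in (0, 14), got {self.pH}")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0 K")
        for name, conc, z in self.added_salt:
            if conc < 0:
                raise InvalidInputError(f"salt {name!r} has negative concentration")
            if z == 0:
                raise InvalidInputError(f"salt {name!r} has zero charge")


def stokes_einstein_diffusivity(r_h: float, solvent: SolventProps) -> float:
    """Diffusion coefficient (m²/s) of a sphere of hydrodynamic radius ``r_h`` (m).

    D = k_B·T / (6π·η·r_h).
    """
    if r_h <= 0:
        raise InvalidInputError(f"hydrodynamic radius must be > 0, got {r_h}")
    return K_B * solvent.temperature / (6.0 * math.pi * solvent.viscosity * r_h)


def radius_from_diffusivity(d: float, solvent: SolventProps) -> float:
    """Hydrodynamic radius (m) of a sphere with diffusion coefficient ``d`` (m²/s)."""
    if d <= 0:
        raise InvalidInputError(f"diffusion coefficient must be > 0, got {d}")
    return K_B * solvent.temperature / (6.0 * math.pi * solvent.viscosity * d)


def phosphate_speciation(pH: float) -> tuple[float, float, float, float]:
    """Molar fractions of (H3PO4, H2PO4⁻, HPO4²⁻, PO4³⁻) at the given pH.

    Computed from the three acid dissociation constants in
    :data:`PHOSPHATE_PKAS` (25 °C values, no activity correction).
    """
    h = 10.0 ** (-pH)
    k1, k2, k3 = (10.0 ** (-pk) for pk in PHOSPHATE_PKAS)
    # Unnormalized populations relative to H3PO4
    w0 = 1.0
    w1 = k1 / h
    w2 = k1 * k2 / h**2
    w3 = k1 * k2 * k3 / h**3
    total = w0 + w1 + w2 + w3
    return (w0 / total, w1 / total, w2 / total, w3 / total)


def ionic_strength(buffer: BufferSpec) -> float:
    """Molar ionic strength I = ½ Σ c_i z_i² of a buffer.

    Phosphate species concentrations follow from the pH via
    :func:`phosphate_speciation`; the Na⁺ counter-ion concentration is set
    by electroneutrality against the phosphate charge.  H⁺/OH⁻ are omitted
    (negligible near neutral pH, and keeps the empty-buffer limit exactly 0).
    """
    _, a1, a2, a3 = phosphate_speciation(buffer.pH)
    p = buffer.phosphate_total
    # charge-weighted phosphate concentrations
    species = [(p * a1, -1), (p * a2, -2), (p * a3, -3)]
    sodium = p * (a1 + 2.0 * a2 + 3.0 * a3)
    species.append((sodium, +1))
    species.extend((conc, z) for _, conc, z in buffer.added_salt)
    return 0.5 * sum(c * z * z for c, z in species)


def debye_length(ionic_strength_molar: float, solvent: SolventProps) -> float:
    """Debye screening length κ⁻¹ (m) in an electrolyte of given ionic strength (M).

    κ⁻¹ = sqrt(ε_r·ε₀·k_B·T / (2·N_A·e²·I·1000)); the factor 1000 converts
    mol/L to mol/m³.
    """
    if ionic_strength_molar <= 0:
        raise InvalidInputError("ionic strength must be > 0 for a Debye length")
    eps = solvent.relative_permittivity * EPS0
    return math.sqrt(
        eps * K_B * solvent.temperature
        / (2.0 * N_A * E_CHARGE**2 * ionic_strength_molar * 1000.0)
    )
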