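"""Unit parsing for configuration values.

Concentrations are stored internally in molar; configuration files and the
CLI accept strings with an explicit unit suffix ("2 uM", "150 μM",
"1.5 mM", "5 nM", "0.02 M").  Bare numbers are rejected so the intended
unit is never ambiguous.
"""

from __future__ import annotations

import re

from .errors import ConfigurationError

_CONC_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,  # μM
    "nM": 1e-9,
    "pM": 1e-12,
}

_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-zμ]+)\s*$")


def parse_concentration(value) -> float:
    """Parse a concentration string with an explicit unit into molar."""
    if isinstance(value, (int, float)):
        raise ConfigurationError(
            f"concentration {value!r} has no unit; write e.g. '{value} uM'"
        )
    m = _CONC_RE.match(str(value))
    if not m:
        raise ConfigurationError(f"cannot parse concentration {value!r}")
    num, unit = m.groups()
    if unit not in _CONC_UNITS:
        raise ConfigurationError(
            f"unknown concentration unit {unit!r} in {value!r}; "
            f"expected one of {sorted(_CONC_UNITS)}"
        )
    try:
        x = float(num)
    except ValueError as err:
        raise ConfigurationError(f"cannot parse concentration {value!r}") from err
    if x < 0:
        raise ConfigurationError(f"concentration must be >= 0, got {value!r}")
    return x * _CONC_UNITS[unit]


def format_concentration(molar: float) -> str:
    """Render a molar concentration with a readable unit."""
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12)):
        if molar >= scale or unit == "pM":
            if molar == 0:
                return "0 M"
            return f"{molar / scale:g} {unit}"
    return f"{molar:g} M"
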