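"""Parsing of value-with-unit strings into strict SI.

Design configs may give quantities either as plain numbers (interpreted as
SI) or as strings such as ``"5.5 MPa"``, ``"4.5 Pa.s"``, ``"250 nm"`` or
``"2 cm"``.  Internally everything is SI: Pa, Pa*s, m, kg/m^3.
"""

from __future__ import annotations

import re

# multiplicative factor to SI, keyed by normalised unit token
_FACTORS = {
    # pressure
    "pa": 1.0,
    "kpa": 1e3,
    "mpa": 1e6,
    "gpa": 1e9,
    # dynamic viscosity
    "pa.s": 1.0,
    "pa*s": 1.0,
    "pas": 1.0,
    "mpa.s": 1e-3,
    "mpa*s": 1e-3,
    "mpas": 1e-3,
    # length
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    # density
    "kg/m3": 1.0,
    "kg/m^3": 1.0,
    "g/cm3": 1e3,
    "g/cm^3": 1e3,
    # frequency
    "hz": 1.0,
    "khz": 1e3,
}

_NUMBER = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*(.*)$")


class UnitError(ValueError):
    """Raised for an unrecognised unit token or malformed quantity string."""


def parse_quantity(value, field: str = "value") -> float:
    """Return ``value`` in SI units.

    Numbers pass through unchanged; strings must be ``"<number> <unit>"``
    with a unit from the supported set (or no unit at all).
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"{field}: cannot interpret {value!r} as a quantity")
    m = _NUMBER.match(value)
    if not m:
        raise UnitError(f"{field}: malformed quantity {value!r}")
    number, unit = float(m.group(1)), m.group(2).strip()
    if not unit:
        return number
    # normalise: lower-case, unicode middle dots to '.'
    token = unit.lower().replace("·", ".").replace("⋅", ".").replace(" ", "")
    if token not in _FACTORS:
        raise UnitError(f"{field}: unknown unit {unit!r} in {value!r}")
    return number * _FACTORS[token]
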