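"""Mass-fraction unit registry and conversions.

Root metabolite contents are reported on three decade-separated scales
(trace sugars in μg/g, sucrose and betaine in mg/g, polysaccharides and
extracts in g/g). Everything is converted to a single canonical unit,
mg per g dry root, on ingest so that downstream arithmetic can never mix
scales.
"""

from __future__ import annotations

from enum import Enum


class Unit(str, Enum):
    """Registered mass-fraction units (analyte mass per g dry root)."""

    UG_PER_G = "ug_per_g"
    MG_PER_G = "mg_per_g"
    G_PER_G = "g_per_g"


#: Canonical internal unit: mg analyte per g dry root.
CANONICAL_UNIT = Unit.MG_PER_G

# decade exponent relative to the canonical mg/g scale
_DECADE = {
    Unit.UG_PER_G: -3,
    Unit.MG_PER_G: 0,
    Unit.G_PER_G: 3,
}


def convert_unit(value: float, from_unit: Unit | str, to_unit: Unit | str) -> float:
    """Rescale ``value`` between registered units.

    Factors are exact powers of ten; upscaling multiplies and
    downscaling divides by the exactly representable integer power, so
    a conversion round trip is correct to within one ulp (and exact for
    the identity conversion).

    Raises
    ------
    ValueError
        If either unit is not registered.
    """
    try:
        f = Unit(from_unit)
        t = Unit(to_unit)
    except ValueError as exc:
        raise ValueError(f"unknown unit in conversion: {exc}") from None
    d = _DECADE[f] - _DECADE[t]
    if d == 0:
        return value
    return value * 10.0**d if d > 0 else value / 10.0**-d


def to_canonical(value: float, unit: Unit | str) -> float:
    """Convert ``value`` from ``unit`` to the canonical mg/g scale."""
    return convert_unit(value, unit, CANONICAL_UNIT)
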