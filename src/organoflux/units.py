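"""Exact scale-factor unit conversions for the internal {μm, s, μM, Pa} system.

All constants entering the solvers are converted to micrometre/second/
micromolar/pascal units on load, so that sparse-matrix entries stay near
unity (a permeability of 1.2e-16 m² becomes 1.2e-4 μm²).
"""

from __future__ import annotations

__all__ = ["convert", "UnitError"]


class UnitError(ValueError):
    """Raised for an unsupported unit or unit pair."""


# Every supported unit maps to (dimension, factor-to-base). Base units per
# dimension: length μm, area μm², time s, pressure Pa, concentration μM,
# density kg/m³, viscosity Pa·s.
_UNITS: dict[str, tuple[str, float]] = {
    "m2": ("area", 1e12),
    "um2": ("area", 1.0),
    "Pa": ("pressure", 1.0),
    "kg/m3": ("density", 1.0),
    "Pa*s": ("viscosity", 1.0),
    "mM": ("concentration", 1e3),
    "uM": ("concentration", 1.0),
    "s": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    "mm": ("length", 1e3),
    "um": ("length", 1.0),
    "nm": ("length", 1e-3),
    "m": ("length", 1e6),
}

# Unicode spellings accepted as aliases for convenience.
_ALIASES = {
    "m²": "m2",
    "μm²": "um2",
    "µm²": "um2",
    "μm2": "um2",
    "μM": "uM",
    "µM": "uM",
    "μm": "um",
    "µm": "um",
    "Pa·s": "Pa*s",
    "Pa.s": "Pa*s",
    "kg/m³": "kg/m3",
}


def _lookup(unit: str) -> tuple[str, float]:
    key = _ALIASES.get(unit, unit)
    try:
        return _UNITS[key]
    except KeyError:
        raise UnitError(f"unsupported unit {unit!r}") from None


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension.

    Conversions are pure scale factors, so round trips are exact to
    machine precision. Identical units return ``value`` unchanged.
    """
    if from_unit == to_unit:
        return value
    dim_a, fac_a = _lookup(from_unit)
    dim_b, fac_b = _lookup(to_unit)
    if dim_a != dim_b:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_a}) to {to_unit!r} ({dim_b})"
        )
    if fac_a == fac_b:
        return value
    # scale by a single ratio, dividing on the downscale leg so that
    # round trips recover the input to the last ulp
    if fac_a > fac_b:
        return value * (fac_a / fac_b)
    return value / (fac_b / fac_a)
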