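"""Physical constants and constitutive laws shared by all solvers.

The porous-media transport model uses three ingredients:

* **Effective diffusivity** ``D_eff = s·ε·D/τ`` — free-solution diffusivity
  ``D`` reduced by liquid saturation ``s``, porosity ``ε`` and tortuosity
  ``τ`` of the medium (τ defaults to 1).
* **Saturation kinetics** — the nanoporous membrane wets gradually; its
  saturation grows linearly in time, ``s(t) = min(s0 + ks·t, 1)``.
* **Darcy permeability** ``k`` — governs pressure-driven leakage flow.

Internal unit system is {μm, s, μM, Pa}: permeabilities are stored in μm²,
diffusivities in μm²/s, concentrations in μM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .units import convert

__all__ = [
    "PorousMaterial",
    "Fluid",
    "Solute",
    "SaturationModel",
    "saturation_at",
    "effective_diffusivity",
    "PETE_MEMBRANE",
    "ORGANOID",
    "AGAROSE",
    "WATER",
    "MAGNEVIST",
    "SULFORHODAMINE_B",
    "IOHEXOL",
    "MEMBRANE_SATURATION",
    "default_constants",
    "dump_constants",
    "load_constants",
]


@dataclass(frozen=True)
class PorousMaterial:
    """A porous domain: porosity ε (–), permeability k (μm²), tortuosity τ (–)."""

    name: str
    porosity: float
    permeability_um2: float
    tortuosity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError(f"porosity must lie in (0, 1], got {self.porosity}")
        if self.permeability_um2 <= 0.0:
            raise ValueError("permeability must be positive")
        if self.tortuosity < 1.0:
            raise ValueError("tortuosity must be >= 1")

    @classmethod
    def from_si(
        cls, name: str, porosity: float, permeability_m2: float, tortuosity: float = 1.0
    ) -> "PorousMaterial":
        """Build from a permeability quoted in m² (the usual literature unit)."""
        return cls(name, porosity, convert(permeability_m2, "m2", "um2"), tortuosity)


@dataclass(frozen=True)
class Fluid:
    """Newtonian fluid: density ρ (kg/m³) and dynamic viscosity η (Pa·s)."""

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class Solute:
    """Solute species: free diffusivity in water D (μm²/s), source concentration (μM)."""

    name: str
    diffusivity: float
    source_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.source_concentration < 0:
            raise ValueError("source concentration must be non-negative")


@dataclass(frozen=True)
class SaturationModel:
    """Linear-in-time membrane wetting, capped at full saturation.

    s(t) = min(s0 + ks·t, 1). The linear law is unbounded, but physical
    saturation cannot exceed 1; the cap is reached at t = (1 − s0)/ks.
    """

    s0: float = 0.075
    ks: float = 3.7e-5  # 1/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.s0 <= 1.0:
            raise ValueError(f"s0 must lie in [0, 1], got {self.s0}")
        if self.ks < 0.0:
            raise ValueError("ks must be non-negative")

    @property
    def saturation_time(self) -> float:
        """Time (s) at which the membrane becomes fully saturated (inf if never)."""
        if self.ks == 0.0:
            return 0.0 if self.s0 >= 1.0 else float("inf")
        return (1.0 - self.s0) / self.ks


def saturation_at(model: SaturationModel, t: float) -> float:
    """Saturation at time ``t`` (s): min(s0 + ks·t, 1); non-decreasing in t."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    return min(model.s0 + model.ks * t, 1.0)


def effective_diffusivity(
    solute: Solute, material: PorousMaterial, s: float = 1.0
) -> float:
    """Effective diffusivity s·ε·D/τ (μm²/s) of ``solute`` in ``material``.

    Fully saturated non-membrane domains use s = 1; the result never
    exceeds the free-solution diffusivity.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"saturation must lie in [0, 1], got {s}")
    return s * material.porosity * solute.diffusivity / material.tortuosity


# ---------------------------------------------------------------------------
# Built-in constants (device materials, water, delivered solutes).
# Permeabilities converted from the literature m² values on load.

PETE_MEMBRANE = PorousMaterial.from_si("pete_membrane", 0.094, 1.2e-16)
ORGANOID = PorousMaterial.from_si("organoid", 0.2, 3.75e-15)
AGAROSE = PorousMaterial.from_si("agarose", 0.99, 8.2e-16)

WATER = Fluid(density=997.0, viscosity=0.0010016)

# Source concentrations in μM: Magnevist 5.6 mM; sulforhodamine B 10 μM;
# iohexol 300 mg/mL at molar mass 821.14 g/mol -> 365.4 mM.
MAGNEVIST = Solute("magnevist", 450.0, convert(5.6, "mM", "uM"))
SULFORHODAMINE_B = Solute("sulforhodamine_b", 470.0, 10.0)
IOHEXOL = Solute("iohexol", 250.0, convert(300.0 / 821.14 * 1e3, "mM", "uM"))

MEMBRANE_SATURATION = SaturationModel(s0=0.075, ks=3.7e-5)


def default_constants() -> dict[str, Any]:
    """The built-in constants table as a plain nested dict (internal units)."""
    return {
        "materials": {
            m.name: asdict(m) for m in (PETE_MEMBRANE, ORGANOID, AGAROSE)
        },
        "fluids": {"water": asdict(WATER)},
        "solutes": {
            s.name: asdict(s) for s in (MAGNEVIST, SULFORHODAMINE_B, IOHEXOL)
        },
        "saturation": asdict(MEMBRANE_SATURATION),
        "units": {
            "length": "um",
            "time": "s",
            "concentration": "uM",
            "pressure": "Pa",
        },
    }


def dump_constants(path: str) -> None:
    """Serialize the resolved constants table to a YAML file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(default_constants(), fh, sort_keys=True)


def load_constants(path: str) -> dict[str, Any]:
    """Load a constants table previously written by :func:`dump_constants`,
    merged over the built-in defaults (partial files override selectively)."""
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    base = default_constants()
    _deep_update(base, user)
    return base


def _deep_update(base: dict, other: dict) -> None:
    for key, val in other.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
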