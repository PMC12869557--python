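"""Shipped experiment presets.

Three delivery experiments are preconfigured, one per solute, each at its
hydrostatic driving pressure: Magnevist into the organoid at 690 Pa, SrB
into the agarose phantom at 510 Pa, and Iohexol into bulk agarose at
196 Pa (300 mg/mL converted at 821.14 g/mol to 365.4 mM).
"""

from __future__ import annotations

from typing import Any

PRESETS: dict[str, dict[str, Any]] = {
    "magnevist-organoid": {
        "mode": "organoid",
        "solute": "magnevist",
        "pressure_Pa": 690.0,
        "tissue": "organoid",
        "delivery_time_s": 3600.0,
    },
    "srb-phantom": {
        "mode": "phantom",
        "solute": "sulforhodamine_b",
        "pressure_Pa": 510.0,
        "tissue": "agarose",
        "output_interval_s": 2400.0,
        "horizon_s": 24000.0,
    },
    "iohexol-agarose": {
        "mode": "agarose-3d",
        "solute": "iohexol",
        "pressure_Pa": 196.0,
        "tissue": "agarose",
        "snapshot_times_s": [0.0, 3600.0, 14400.0, 86400.0],
    },
}

PRESSURE_PRESETS_PA = (690.0, 510.0, 196.0)


def get_preset(name: str) -> dict[str, Any]:
    try:
        return dict(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
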