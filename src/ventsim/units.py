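"""Canonical physical-quantity conventions shared by every module.

Internal canonical units
------------------------
* pressure — millibar (mbar), gauge (atmosphere = 0).  Test-lung
  resistance/compliance are natively quoted in mbar-based units, so mbar
  is the least-conversion choice; clinical setpoints entered in mmHg are
  converted once, at the configuration boundary.
* flow — standard liters per minute (SLPM), the span unit of the
  inspiratory flow sensor.  Flows are "standard": no density correction
  is applied between SLPM and volumetric mL/s, since gas downstream of
  the regulator is treated as incompressible.
* volume — milliliters above resting lung volume.

All conversions are fixed linear factors and round-trip to 1e-9
relative error.
"""

from __future__ import annotations

import math

__all__ = [
    "ConfigurationError",
    "PSI_TO_MBAR",
    "MMHG_TO_MBAR",
    "CMH2O_TO_MBAR",
    "MBAR_TO_PA",
    "convert_pressure",
    "convert_flow",
    "mmhg",
    "psi",
    "slpm_to_ml_per_s",
    "ml_per_s_to_slpm",
]


class ConfigurationError(ValueError):
    """Raised for invalid configuration: unknown units, bad setpoints,
    inconsistent sampling, or an unstable integration step."""


PSI_TO_MBAR = 68.9476
MMHG_TO_MBAR = 1.33322
CMH2O_TO_MBAR = 0.980665
MBAR_TO_PA = 100.0

# factors into the canonical unit
_PRESSURE_TO_MBAR = {
    "mbar": 1.0,
    "psi": PSI_TO_MBAR,
    "mmHg": MMHG_TO_MBAR,
    "cmH2O": CMH2O_TO_MBAR,
}

_FLOW_TO_SLPM = {
    "SLPM": 1.0,
    "mL_per_s": 60.0 / 1000.0,   # 1 mL/s = 0.06 SLPM
    "m3_per_s": 60000.0,         # 1 m³/s = 60000 L/min
}


def _factor(table: dict[str, float], unit: str, kind: str) -> float:
    try:
        return table[unit]
    except KeyError:
        known = ", ".join(sorted(table))
        raise ConfigurationError(
            f"unknown {kind} unit {unit!r}; expected one of: {known}"
        ) from None


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a gauge pressure between psi, mmHg, mbar and cmH2O.

    Parameters
    ----------
    value
        Finite pressure in `from_unit`.
    from_unit, to_unit
        One of ``"psi"``, ``"mmHg"``, ``"mbar"``, ``"cmH2O"``.
    """
    if not math.isfinite(value):
        raise ConfigurationError(f"pressure must be finite, got {value!r}")
    f = _factor(_PRESSURE_TO_MBAR, from_unit, "pressure")
    t = _factor(_PRESSURE_TO_MBAR, to_unit, "pressure")
    return value * f / t


def convert_flow(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a volumetric flow between SLPM, mL/s and m³/s."""
    if not math.isfinite(value):
        raise ConfigurationError(f"flow must be finite, got {value!r}")
    f = _factor(_FLOW_TO_SLPM, from_unit, "flow")
    t = _factor(_FLOW_TO_SLPM, to_unit, "flow")
    return value * f / t


def mmhg(value: float) -> float:
    """mmHg → mbar shorthand for clinical setpoints."""
    return convert_pressure(value, "mmHg", "mbar")


def psi(value: float) -> float:
    """psi → mbar shorthand for supply/regulator pressures."""
    return convert_pressure(value, "psi", "mbar")


def slpm_to_ml_per_s(q: float) -> float:
    return q * 1000.0 / 60.0


def ml_per_s_to_slpm(q: float) -> float:
    return q * 60.0 / 1000.0
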