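"""Gas path: supply → relieving regulator → needle valve → solenoids.

The inspiratory limb is driven by a relieving pressure regulator (output
never exceeds its 0–2 psi setpoint) feeding a needle valve whose orifice
obeys laminar Hagen–Poiseuille flow,

    Q = Δp · A² / (8π µ L),

with Δp the pressure drop across the valve, A the orifice area, µ the
dynamic viscosity and L the restriction length.  Oxygen fraction is set
by static blending of a compressed-air line (21 % O₂) and a pure-oxygen
line.  Two binary solenoid valves gate inspiration and expiration; the
split-tubing topology makes every flow one-way.

The expiratory limb is a fixed linear resistance to ambient, not a
needle valve: adding a needle valve there would add large relative
resistance against the much smaller expiratory pressure gradient, so
the real device omits it and so do we.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import ConfigurationError, psi

__all__ = [
    "O2_FRACTION_AIR",
    "GasSupply",
    "RegulatorSetting",
    "NeedleValveGeometry",
    "SolenoidState",
    "regulator_output",
    "poiseuille_flow",
    "blend_fio2",
    "path_flow",
]

O2_FRACTION_AIR = 0.21

_REGULATOR_BAND_MBAR = psi(2.0)  # regulators convert supply down to 0–2 psi


@dataclass(frozen=True)
class GasSupply:
    """Compressed gas line: wall air or oxygen at roughly 50 psi."""

    pressure: float = psi(50.0)          # mbar gauge
    oxygen_fraction: float = O2_FRACTION_AIR

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ConfigurationError(f"supply pressure must be positive, got {self.pressure}")
        if not (O2_FRACTION_AIR <= self.oxygen_fraction <= 1.0):
            raise ConfigurationError(
                f"oxygen fraction must lie in [0.21, 1.0], got {self.oxygen_fraction}"
            )


@dataclass(frozen=True)
class RegulatorSetting:
    """Relieving-regulator output setpoint, constrained to the 0–2 psi band."""

    output_setpoint: float  # mbar

    def __post_init__(self) -> None:
        if not (0.0 <= self.output_setpoint <= _REGULATOR_BAND_MBAR + 1e-9):
            raise ConfigurationError(
                f"regulator setpoint {self.output_setpoint:.3f} mbar outside the "
                f"0–{_REGULATOR_BAND_MBAR:.3f} mbar (0–2 psi) band"
            )


@dataclass(frozen=True)
class NeedleValveGeometry:
    """Needle-valve restriction: orifice area A (m²), length L (m), gas viscosity µ (Pa·s)."""

    orifice_area: float
    tube_length: float = 0.1
    dynamic_viscosity: float = 1.81e-5  # air at ~15 °C

    def __post_init__(self) -> None:
        if not (self.orifice_area > 0 and self.tube_length > 0 and self.dynamic_viscosity > 0):
            raise ConfigurationError("needle-valve geometry must be strictly positive")

    @property
    def conductance_si(self) -> float:
        """A²/(8πµL) in (m³/s)/Pa."""
        return self.orifice_area**2 / (8.0 * math.pi * self.dynamic_viscosity * self.tube_length)

    @property
    def conductance(self) -> float:
        """Valve conductance in (L/s)/mbar (1 mbar = 100 Pa, 1 m³ = 1000 L)."""
        return self.conductance_si * 100.0 * 1000.0

    @property
    def equivalent_resistance(self) -> float:
        """1/conductance, in mbar/(L·s) — comparable to lung resistance."""
        return 1.0 / self.conductance

    @classmethod
    def for_max_flow(
        cls,
        max_flow_slpm: float = 100.0,
        drive_pressure: float = psi(2.0),
        tube_length: float = 0.1,
        dynamic_viscosity: float = 1.81e-5,
    ) -> "NeedleValveGeometry":
        """Calibrate the orifice so fully-open flow into an empty lung at the
        given drive pressure equals ``max_flow_slpm`` (default: the 100 SLPM
        flow-sensor span at the 2 psi regulator ceiling).  The physical
        orifice dimensions are not published; this is a documented
        calibration choice, overridable in config."""
        q_m3s = max_flow_slpm / 60000.0
        dp_pa = drive_pressure * 100.0
        area = math.sqrt(q_m3s * 8.0 * math.pi * dynamic_viscosity * tube_length / dp_pa)
        return cls(orifice_area=area, tube_length=tube_length, dynamic_viscosity=dynamic_viscosity)


@dataclass(frozen=True)
class SolenoidState:
    """Binary solenoid commands; no partial opening."""

    inspiratory_open: bool = False
    expiratory_open: bool = False


def regulator_output(supply: GasSupply, setting: RegulatorSetting) -> float:
    """Downstream pressure of a relieving regulator, in mbar.

    Relieving behavior: output tracks the setpoint and never exceeds it,
    regardless of supply pressure; it also cannot exceed the supply.
    """
    return min(supply.pressure, setting.output_setpoint)


def poiseuille_flow(delta_p: float, geom: NeedleValveGeometry) -> float:
    """Laminar orifice flow Q = Δp·A²/(8πµL), returned in SLPM.

    ``delta_p`` is in mbar.  Negative gradients return 0: the
    solenoid/check topology enforces one-way flow.
    """
    if delta_p <= 0:
        return 0.0
    q_m3s = (delta_p * 100.0) * geom.conductance_si
    return q_m3s * 60000.0


def blend_fio2(air_flow: float, o2_flow: float) -> float:
    """Oxygen fraction of a blend of air (21 % O₂) and pure-oxygen flows.

    Flow-weighted mixing; result spans [0.21, 1.0] from pure air to pure
    oxygen.  Both flows zero is an undefined mixture.
    """
    if air_flow < 0 or o2_flow < 0:
        raise ConfigurationError("blend flows must be non-negative")
    total = air_flow + o2_flow
    if total == 0:
        raise ConfigurationError("undefined mixture: both blend flows are zero")
    return (O2_FRACTION_AIR * air_flow + 1.0 * o2_flow) / total


def path_flow(
    solenoids: SolenoidState,
    drive_pressure: float,
    alveolar_pressure: float,
    lung_resistance: float,
    geom: NeedleValveGeometry,
    expiratory_resistance: float,
    ambient_pressure: float = 0.0,
) -> tuple[float, float]:
    """Inspiratory and expiratory flows (SLPM) through the open solenoids.

    The instantaneous airway pressure depends on the flow itself
    (P_aw = P_alv + R_lung·Q), so each limb is solved as a series
    pressure balance rather than fed back across samples (which is
    unstable when lung resistance exceeds the path resistance):

    * inspiration — needle valve (conductance G) in series with the lung:
      ``Q = G·(P_drive − P_alv) / (1 + G·R_lung)``;
    * expiration — lung resistance in series with the fixed expiratory
      resistance to ambient: ``Q = (P_alv − P_amb) / (R_lung + R_exp)``.

    Both flows are clamped non-negative (unidirectional contract).  As
    the lung inflates P_alv rises, so inspiratory flow falls — the
    device's operating principle.
    """
    if expiratory_resistance <= 0:
        raise ConfigurationError("expiratory resistance must be positive")
    inflow = 0.0
    outflow = 0.0
    if solenoids.inspiratory_open:
        g = geom.conductance  # (L/s)/mbar
        q_ls = g * (drive_pressure - alveolar_pressure) / (1.0 + g * lung_resistance)
        inflow = max(q_ls, 0.0) * 60.0
    if solenoids.expiratory_open:
        q_ls = (alveolar_pressure - ambient_pressure) / (lung_resistance + expiratory_resistance)
        outflow = max(q_ls, 0.0) * 60.0
    return inflow, outflow
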