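"""YAML scenario configuration with explicit unit tags.

Dimensional quantities are written as ``{value: <num>, unit: <tag>}``
mappings — never bare numbers — so configs are unambiguous about psi vs
mmHg vs mbar.  Dimensionless settings (I/E, FiO2 fraction, seed) and
fixed-unit counts (rr in bpm, sample_rate in Hz) are plain scalars.

Example::

    settings:
      mode: pressure
      pip:  {value: 14, unit: mmHg}
      peep: {value: 2, unit: mmHg}
      rr: 12
      ie_ratio: 2.0
      fio2_target: 0.40
    lung:
      resistance: {value: 10, unit: mbar_per_L_s}
      compliance: {value: 30, unit: mL_per_mbar}
      capacity:   {value: 1000, unit: mL}
    pneumatics:
      regulator: {value: 2, unit: psi}
      valve: {max_flow_slpm: 100}
      expiratory_resistance: {value: 5, unit: mbar_per_L_s}
    simulation:
      duration: {value: 60, unit: s}
      seed: 1
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .controller import Mode, VentSettings
from .engine import Scenario
from .lung import LungParams
from .pneumatics import GasSupply, NeedleValveGeometry, RegulatorSetting
from .sensing import FLOW_SENSOR, O2_SENSOR, PRESSURE_SENSOR, SensorSpec
from .units import ConfigurationError, convert_pressure

__all__ = ["load_scenario", "scenario_from_dict"]


def _quantity(node: Any, where: str) -> tuple[float, str]:
    if not isinstance(node, Mapping) or set(node) != {"value", "unit"}:
        raise ConfigurationError(
            f"{where}: dimensional quantities must be '{{value: <num>, unit: <tag>}}' "
            f"mappings, got {node!r}"
        )
    return float(node["value"]), str(node["unit"])


def _pressure_mbar(node: Any, where: str) -> float:
    value, unit = _quantity(node, where)
    return convert_pressure(value, unit, "mbar")


def _fixed_unit(node: Any, expected: str, where: str) -> float:
    value, unit = _quantity(node, where)
    if unit != expected:
        raise ConfigurationError(f"{where}: expected unit {expected!r}, got {unit!r}")
    return value


def scenario_from_dict(cfg: Mapping[str, Any]) -> Scenario:
    """Build a :class:`~ventsim.engine.Scenario` from a parsed config mapping."""
    s = cfg.get("settings", {})
    settings = VentSettings(
        mode=Mode(s.get("mode", "pressure")),
        pip=_pressure_mbar(s["pip"], "settings.pip"),
        peep=_pressure_mbar(s["peep"], "settings.peep"),
        rr=float(s.get("rr", 20)),
        ie_ratio=float(s.get("ie_ratio", 1.0)),
        fio2_target=float(s.get("fio2_target", 0.21)),
        vt_setpoint=(
            _fixed_unit(s["vt_setpoint"], "mL", "settings.vt_setpoint")
            if "vt_setpoint" in s
            else None
        ),
        sample_rate=float(s.get("sample_rate", 200.0)),
        pip_hold=bool(s.get("pip_hold", True)),
        hysteresis_mbar=float(s.get("hysteresis_mbar", 0.0)),
    )

    l = cfg.get("lung", {})
    lung = LungParams(
        resistance=_fixed_unit(l["resistance"], "mbar_per_L_s", "lung.resistance"),
        compliance=_fixed_unit(l["compliance"], "mL_per_mbar", "lung.compliance"),
        capacity=(
            _fixed_unit(l["capacity"], "mL", "lung.capacity") if "capacity" in l else 1000.0
        ),
    )

    p = cfg.get("pneumatics", {})
    kwargs: dict[str, Any] = {"settings": settings, "lung": lung}
    if "regulator" in p:
        kwargs["regulator"] = RegulatorSetting(_pressure_mbar(p["regulator"], "pneumatics.regulator"))
    if "supply_air" in p:
        kwargs["supply_air"] = GasSupply(
            pressure=_pressure_mbar(p["supply_air"]["pressure"], "pneumatics.supply_air"),
            oxygen_fraction=0.21,
        )
    if "supply_o2" in p:
        kwargs["supply_o2"] = GasSupply(
            pressure=_pressure_mbar(p["supply_o2"]["pressure"], "pneumatics.supply_o2"),
            oxygen_fraction=1.0,
        )
    if "valve" in p:
        v = p["valve"]
        if "max_flow_slpm" in v:
            drive = kwargs.get("regulator", RegulatorSetting(convert_pressure(2, "psi", "mbar")))
            kwargs["valve"] = NeedleValveGeometry.for_max_flow(
                max_flow_slpm=float(v["max_flow_slpm"]), drive_pressure=drive.output_setpoint
            )
        else:
            kwargs["valve"] = NeedleValveGeometry(
                orifice_area=float(v["orifice_area_m2"]),
                tube_length=float(v.get("tube_length_m", 0.1)),
                dynamic_viscosity=float(v.get("dynamic_viscosity_pa_s", 1.81e-5)),
            )
    if "expiratory_resistance" in p:
        kwargs["expiratory_resistance"] = _fixed_unit(
            p["expiratory_resistance"], "mbar_per_L_s", "pneumatics.expiratory_resistance"
        )

    sensors = cfg.get("sensors", {})
    for key, default, attr in [
        ("flow", FLOW_SENSOR, "flow_sensor"),
        ("pressure", PRESSURE_SENSOR, "pressure_sensor"),
        ("o2", O2_SENSOR, "o2_sensor"),
    ]:
        if key in sensors:
            n = sensors[key]
            kwargs[attr] = SensorSpec(
                lo=float(n.get("lo", default.lo)),
                hi=float(n.get("hi", default.hi)),
                noise_sd=float(n.get("noise_sd", 0.0)),
            )

    sim = cfg.get("simulation", {})
    if "duration" in sim:
        kwargs["duration"] = _fixed_unit(sim["duration"], "s", "simulation.duration")
    if "seed" in sim:
        kwargs["seed"] = int(sim["seed"])
    return Scenario(**kwargs)


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return scenario_from_dict(cfg)
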