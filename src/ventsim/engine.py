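"""Closed-loop fixed-step simulation: controller → valves → lung → sensors.

Each sample applies, in order, the controller step (acting on the
*previous* sample's sensor readings — one sample of loop latency, as in
the real sampled system), the pneumatic path flows for the commanded
solenoid states, one explicit Euler lung update, and the sensor reads
that the controller will see next sample.  The result is a uniformly
sampled waveform table plus per-breath summary metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import ControllerState, Mode, Phase, VentSettings, breath_timing, controller_step
from .lung import LungParams, LungState, lung_step
from .pneumatics import (
    O2_FRACTION_AIR,
    GasSupply,
    NeedleValveGeometry,
    RegulatorSetting,
    SolenoidState,
    blend_fio2,
    path_flow,
    regulator_output,
)
from .sensing import FLOW_SENSOR, O2_SENSOR, PRESSURE_SENSOR, SensorReading, SensorSpec, sensor_read
from .units import ConfigurationError, convert_pressure, psi

__all__ = ["Scenario", "sheep_scenario", "simulate", "breath_metrics", "WAVEFORM_COLUMNS"]

WAVEFORM_COLUMNS = [
    "time_s",
    "pressure_mbar",        # sensed lung pressure — the controlled variable
    "pressure_mmhg",
    "airway_pressure_mbar",  # true mouth pressure incl. resistive drop R·Q
    "flow_slpm",
    "volume_ml",
    "phase",
    "breath_index",
    "insp_valve",
    "exp_valve",
    "fio2",
    "over_inflated",
]


@dataclass(frozen=True)
class Scenario:
    """Complete closed-loop configuration.

    The inspiratory needle valve defaults to the calibration that yields
    the flow sensor's 100 SLPM span at the 2 psi regulator ceiling into
    an empty lung.  ``expiratory_resistance`` lumps the expiratory
    solenoid, tubing and exhaust path (mbar/(L·s)).
    """

    settings: VentSettings
    lung: LungParams
    supply_air: GasSupply = GasSupply(oxygen_fraction=0.21)
    supply_o2: GasSupply = GasSupply(oxygen_fraction=1.0)
    regulator: RegulatorSetting = RegulatorSetting(output_setpoint=psi(2.0))
    valve: NeedleValveGeometry = field(default_factory=NeedleValveGeometry.for_max_flow)
    expiratory_resistance: float = 5.0
    flow_sensor: SensorSpec = FLOW_SENSOR
    pressure_sensor: SensorSpec = PRESSURE_SENSOR
    o2_sensor: SensorSpec = O2_SENSOR
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        t_insp, t_exp = breath_timing(self.settings.rr, self.settings.ie_ratio)
        if self.duration < t_insp + t_exp:
            raise ConfigurationError(
                f"duration {self.duration} s shorter than one breath cycle "
                f"({t_insp + t_exp:.2f} s)"
            )
        if self.expiratory_resistance <= 0:
            raise ConfigurationError("expiratory_resistance must be positive")

    @property
    def drive_pressure(self) -> float:
        """Regulated inspiratory drive pressure (mbar), constant within a breath."""
        supply = min(self.supply_air.pressure, self.supply_o2.pressure)
        return regulator_output(GasSupply(pressure=supply), self.regulator)

    def o2_flow_share(self) -> float:
        """Fraction of total inspiratory flow drawn from the oxygen line so
        the static blend meets ``settings.fio2_target``."""
        return (self.settings.fio2_target - O2_FRACTION_AIR) / (1.0 - O2_FRACTION_AIR)

    def min_time_constant(self) -> float:
        """Smallest RC time constant of either breath phase, seconds."""
        r_insp = self.valve.equivalent_resistance + self.lung.resistance
        r_exp = self.lung.resistance + self.expiratory_resistance
        return min(r_insp, r_exp) * self.lung.compliance / 1000.0


def sheep_scenario(
    duration: float = 60.0,
    seed: int = 0,
    rr: float = 12.0,
    **overrides,
) -> Scenario:
    """In vivo large-animal configuration.

    Controller setpoints follow the animal protocol: PEEP 2 mmHg, FiO2
    40 %, PIP / RR / I/E fixed mid-range of the reported operating bands
    (PIP 14 mmHg, RR 12 bpm, I/E 2.0 — inspiratory-dominant, taken
    literally).  The sheep's respiratory mechanics were not measured;
    R = 10 mbar/(L·s), C = 30 mL/mbar are documented fixture defaults.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # I/E > 1 is deliberate here
        settings = VentSettings(
            mode=Mode.PRESSURE,
            pip=convert_pressure(14.0, "mmHg", "mbar"),
            peep=convert_pressure(2.0, "mmHg", "mbar"),
            rr=rr,
            ie_ratio=2.0,
            fio2_target=0.40,
        )
    kwargs = dict(
        settings=settings,
        lung=LungParams(resistance=10.0, compliance=30.0),
        duration=duration,
        seed=seed,
    )
    kwargs.update(overrides)
    return Scenario(**kwargs)


def simulate(scenario: Scenario) -> pd.DataFrame:
    """Run the closed loop and return the sampled waveform table.

    Deterministic given ``scenario.seed``.  Columns are
    ``WAVEFORM_COLUMNS``: time, sensed lung pressure (mbar and mmHg —
    the signal the controller gates on), true airway (mouth) pressure
    including the resistive drop, sensed inspiratory flow (SLPM), true
    lung volume (mL), controller phase and breath index, solenoid
    commands, sensed oxygen fraction, and the over-inflation flag.
    """
    settings = scenario.settings
    dt = settings.dt
    tau = scenario.min_time_constant()
    if dt > tau / 5.0:
        raise ConfigurationError(
            f"unstable configuration: dt={dt:.4g} s exceeds τ/5={tau / 5.0:.4g} s "
            "for the fastest phase; raise sample_rate or slow the pneumatics"
        )

    n = round(scenario.duration * settings.sample_rate)
    rng = np.random.default_rng(scenario.seed)
    drive = scenario.drive_pressure

    # static FiO2 blend from the air/oxygen needle-valve flow split
    s = scenario.o2_flow_share()
    fio2_true = blend_fio2(1.0 - s, s) if s > 0 else O2_FRACTION_AIR
    fio2_sensed = sensor_read(fio2_true, scenario.o2_sensor, rng).value

    lung_state = LungState()
    cstate = ControllerState()
    p_read = SensorReading(time=-dt, value=0.0, saturated=False)
    f_read = SensorReading(time=-dt, value=0.0, saturated=False)

    time = np.arange(n) * dt
    pressure = np.empty(n)
    airway = np.empty(n)
    flow = np.empty(n)
    volume = np.empty(n)
    phase = np.empty(n, dtype=np.uint8)
    breath = np.empty(n, dtype=np.int32)
    insp_valve = np.empty(n, dtype=bool)
    exp_valve = np.empty(n, dtype=bool)
    over = np.empty(n, dtype=bool)

    r_lung = scenario.lung.resistance
    for k in range(n):
        cstate, sol = controller_step(cstate, p_read, f_read, settings, dt)
        inflow, outflow = path_flow(
            sol,
            drive,
            lung_state.alveolar_pressure,
            r_lung,
            scenario.valve,
            scenario.expiratory_resistance,
        )
        lung_state = lung_step(lung_state, scenario.lung, inflow, outflow, dt)
        t = time[k]
        # the transducer monitors lung pressure (the compartment pressure),
        # which is what PIP/PEEP threshold gating acts on
        p_read = sensor_read(lung_state.alveolar_pressure, scenario.pressure_sensor, rng, t)
        f_read = sensor_read(inflow, scenario.flow_sensor, rng, t)

        pressure[k] = p_read.value
        airway[k] = lung_state.airway_pressure
        flow[k] = f_read.value
        volume[k] = lung_state.volume
        phase[k] = 1 if cstate.phase is Phase.INSPIRATION else 0
        breath[k] = cstate.breath_index
        insp_valve[k] = sol.inspiratory_open
        exp_valve[k] = sol.expiratory_open
        over[k] = lung_state.over_inflated

    return pd.DataFrame(
        {
            "time_s": time,
            "pressure_mbar": pressure,
            "pressure_mmhg": convert_pressure(1.0, "mbar", "mmHg") * pressure,
            "airway_pressure_mbar": airway,
            "flow_slpm": flow,
            "volume_ml": volume,
            "phase": np.where(phase == 1, Phase.INSPIRATION.value, Phase.EXPIRATION.value),
            "breath_index": breath,
            "insp_valve": insp_valve,
            "exp_valve": exp_valve,
            "fio2": fio2_sensed,
            "over_inflated": over,
        }
    )


def breath_metrics(record: pd.DataFrame) -> pd.DataFrame:
    """Per-breath summary statistics from a simulated waveform.

    One row per *completed* breath (a breath is complete once the next
    one has started): maximum and mean inspiratory flow, delivered V_T
    (trapezoidal integral of sensed flow over the controller-logged
    inspiratory window), achieved PIP (max sensed lung pressure) and PEEP
    (end-expiratory sensed lung pressure) in mmHg, and the realized rate and
    I/E from the phase log.  Start-up transients mean the first breath
    is conventionally dropped from steady-state summaries by callers.
    """
    from .sensing import integrate_tidal_volume

    if record.empty:
        warnings.warn("empty waveform: no breaths to summarize", UserWarning, stacklevel=2)
        return _empty_metrics()
    last_breath = int(record["breath_index"].iloc[-1])
    completed = range(0, last_breath)  # the final (in-progress) breath is excluded
    rows = []
    t = record["time_s"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else float("nan")
    for b in completed:
        sel = record[record["breath_index"] == b]
        insp = sel[sel["phase"] == Phase.INSPIRATION.value]
        exp = sel[sel["phase"] == Phase.EXPIRATION.value]
        if insp.empty or exp.empty:
            continue
        samples = np.column_stack([insp["time_s"].to_numpy(), insp["flow_slpm"].to_numpy()])
        vt = integrate_tidal_volume(samples)
        t_insp = len(insp) * dt
        t_exp = len(exp) * dt
        rows.append(
            {
                "breath_index": b,
                "max_insp_flow_slpm": float(insp["flow_slpm"].max()),
                "mean_insp_flow_slpm": float(insp["flow_slpm"].mean()),
                "delivered_vt_ml": vt,
                "achieved_pip_mmhg": float(sel["pressure_mmhg"].max()),
                "achieved_peep_mmhg": float(exp["pressure_mmhg"].iloc[-1]),
                "measured_rr_bpm": 60.0 / (t_insp + t_exp),
                "measured_ie": t_insp / t_exp,
                "over_inflated": bool(sel["over_inflated"].any()),
            }
        )
    if not rows:
        warnings.warn("no completed breath in record", UserWarning, stacklevel=2)
        return _empty_metrics()
    return pd.DataFrame(rows)


def _empty_metrics() -> pd.DataFrame:
    cols = [
        "breath_index",
        "max_insp_flow_slpm",
        "mean_insp_flow_slpm",
        "delivered_vt_ml",
        "achieved_pip_mmhg",
        "achieved_peep_mmhg",
        "measured_rr_bpm",
        "measured_ie",
        "over_inflated",
    ]
    return pd.DataFrame(columns=cols)
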