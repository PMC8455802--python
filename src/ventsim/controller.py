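"""Sampled breath-cycle controller: threshold gating of the two solenoids.

The control law mirrors the device's software loop.  Breath timing is
clock-driven from RR and I/E — thresholds only gate valves *within* a
phase, so pressure events can never change the set rate.  Within
inspiration the inspiratory solenoid is bang-bang gated: in pressure
mode it closes when sensed lung pressure reaches PIP and (by default)
re-opens when pressure sags below it, holding a plateau; in volume mode
it closes once the integrated delivered volume reaches the V_T setpoint
and stays closed for the rest of the phase.  Within expiration the
expiratory solenoid vents until sensed pressure falls to PEEP, then
holds.  Expiration time and PEEP are therefore coupled exactly as in
the device — the simulator reproduces, not fixes, this limitation.

The two solenoids are never commanded open in the same sample.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .pneumatics import O2_FRACTION_AIR, SolenoidState
from .sensing import SensorReading
from .units import ConfigurationError

__all__ = ["Mode", "Phase", "VentSettings", "ControllerState", "breath_timing", "controller_step"]

_ML_PER_SLPM_S = 1000.0 / 60.0  # 1 SLPM sustained for 1 s delivers 16.67 mL


class Mode(str, enum.Enum):
    PRESSURE = "pressure"
    VOLUME = "volume"


class Phase(str, enum.Enum):
    INSPIRATION = "INSPIRATION"
    EXPIRATION = "EXPIRATION"


@dataclass(frozen=True)
class VentSettings:
    """Clinician-facing setpoints.

    pip, peep       : mbar (convert clinical mmHg at the config boundary).
    rr              : breaths/min.
    ie_ratio        : t_insp : t_exp.  Values > 1 (inspiration longer than
                      expiration) are accepted literally but flagged with a
                      warning, since they invert clinical convention.
    fio2_target     : inspired-oxygen fraction in [0.21, 1.0].
    vt_setpoint     : mL, required in volume mode.
    sample_rate     : Hz; > 100 Hz advised, 200 Hz default.
    pip_hold        : bang-bang hold at PIP (True, default) vs single-shot
                      close for the rest of the phase (False).
    hysteresis_mbar : optional re-opening band below PIP / above PEEP; the
                      default 0 leaves only the natural one-sample hysteresis.
    """

    mode: Mode = Mode.PRESSURE
    pip: float = 20.0
    peep: float = 0.0
    rr: float = 20.0
    ie_ratio: float = 1.0
    fio2_target: float = O2_FRACTION_AIR
    vt_setpoint: float | None = None
    sample_rate: float = 200.0
    pip_hold: bool = True
    hysteresis_mbar: float = 0.0

    def __post_init__(self) -> None:
        mode = Mode(self.mode)
        object.__setattr__(self, "mode", mode)
        if not (0.0 <= self.peep < self.pip):
            raise ConfigurationError(f"require 0 <= PEEP < PIP, got peep={self.peep}, pip={self.pip}")
        if self.rr <= 0 or self.ie_ratio <= 0:
            raise ConfigurationError("rr and ie_ratio must be positive")
        if not (O2_FRACTION_AIR <= self.fio2_target <= 1.0):
            raise ConfigurationError(f"fio2_target must lie in [0.21, 1.0], got {self.fio2_target}")
        if self.sample_rate < 100.0:
            raise ConfigurationError(
                f"sample_rate {self.sample_rate} Hz below the advised minimum of 100 Hz"
            )
        if mode is Mode.VOLUME and not (self.vt_setpoint and self.vt_setpoint > 0):
            raise ConfigurationError("volume mode requires a positive vt_setpoint")
        if self.hysteresis_mbar < 0:
            raise ConfigurationError("hysteresis_mbar must be non-negative")
        if self.ie_ratio > 1.0:
            warnings.warn(
                f"I/E ratio {self.ie_ratio} > 1 makes inspiration longer than expiration "
                "(inverted relative to clinical convention); interpreted literally as t_insp:t_exp",
                UserWarning,
                stacklevel=2,
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def phase_sample_counts(self) -> tuple[int, int]:
        """Samples per inspiratory / expiratory phase at the set clock."""
        t_insp, t_exp = breath_timing(self.rr, self.ie_ratio)
        n_cycle = round((t_insp + t_exp) * self.sample_rate)
        n_insp = min(max(round(t_insp * self.sample_rate), 1), n_cycle - 1)
        return n_insp, n_cycle - n_insp


def breath_timing(rr: float, ie_ratio: float) -> tuple[float, float]:
    """Phase durations (t_insp, t_exp) in seconds from RR and I/E.

    t_cycle = 60/RR; t_insp = t_cycle · I/E / (1 + I/E).
    """
    if rr <= 0 or ie_ratio <= 0:
        raise ConfigurationError("rr and ie_ratio must be positive")
    t_cycle = 60.0 / rr
    t_insp = t_cycle * ie_ratio / (1.0 + ie_ratio)
    return t_insp, t_cycle - t_insp


@dataclass(frozen=True)
class ControllerState:
    """Breath-phase finite-state machine state.

    ``phase_samples`` counts completed samples in the current phase;
    ``phase_elapsed`` (seconds) derives from it, keeping the clock free
    of floating-point drift.  ``delivered_volume_this_breath`` is the
    controller's own rectangle-rule integral of sensed flow, the signal
    used for V_T gating.
    """

    phase: Phase = Phase.INSPIRATION
    phase_samples: int = 0
    breath_index: int = 0
    delivered_volume_this_breath: float = 0.0
    pip_reached: bool = False
    peep_holding: bool = False

    def phase_elapsed(self, dt: float) -> float:
        return self.phase_samples * dt


def controller_step(
    cstate: ControllerState,
    pressure_reading: SensorReading,
    flow_reading: SensorReading,
    settings: VentSettings,
    dt: float,
) -> tuple[ControllerState, SolenoidState]:
    """One control-loop iteration: update the FSM and command the solenoids.

    Readings are the previous physics sample's sensor outputs (one-sample
    loop latency, as in the real sampled system).  Returns the successor
    state and the valve commands to apply over the coming sample.
    """
    if abs(dt * settings.sample_rate - 1.0) > 1e-9:
        raise ConfigurationError(
            f"dt={dt} inconsistent with sample_rate={settings.sample_rate} Hz"
        )
    n_insp, n_exp = settings.phase_sample_counts()

    phase = cstate.phase
    phase_samples = cstate.phase_samples
    breath_index = cstate.breath_index
    delivered = cstate.delivered_volume_this_breath
    pip_reached = cstate.pip_reached

    # the incoming flow reading covers the previous sample, attribute it
    # to the phase that produced it before any transition
    if phase is Phase.INSPIRATION:
        delivered += flow_reading.value * _ML_PER_SLPM_S * dt

    # clock-driven phase transitions
    if phase is Phase.INSPIRATION and phase_samples >= n_insp:
        phase, phase_samples = Phase.EXPIRATION, 0
    elif phase is Phase.EXPIRATION and phase_samples >= n_exp:
        phase, phase_samples = Phase.INSPIRATION, 0
        breath_index += 1
        delivered = 0.0
        pip_reached = False

    p = pressure_reading.value
    insp_open = False
    exp_open = False
    peep_holding = False
    if phase is Phase.INSPIRATION:
        if settings.mode is Mode.VOLUME:
            insp_open = delivered < settings.vt_setpoint
            if p >= settings.pip:
                pip_reached = True
        else:
            if p >= settings.pip:
                pip_reached = True
                insp_open = False
            elif pip_reached and not settings.pip_hold:
                insp_open = False  # single-shot: stay closed for the phase
            elif pip_reached and settings.hysteresis_mbar > 0:
                insp_open = p < settings.pip - settings.hysteresis_mbar
            else:
                insp_open = True
    else:
        exp_open = p > settings.peep + settings.hysteresis_mbar
        peep_holding = not exp_open

    new_state = ControllerState(
        phase=phase,
        phase_samples=phase_samples + 1,
        breath_index=breath_index,
        delivered_volume_this_breath=delivered,
        pip_reached=pip_reached,
        peep_holding=peep_holding,
    )
    return new_state, SolenoidState(inspiratory_open=insp_open, expiratory_open=exp_open)
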