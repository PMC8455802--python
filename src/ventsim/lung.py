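"""Single-compartment resistance–compliance test-lung model.

Emulates a 1 L artificial test lung with selectable airway resistance
(mbar/(L·s)) and linear compliance (mL/mbar).  State is the inflated
volume above resting volume; alveolar pressure follows the compliance
relation P_alv = V/C and airway (mouth) pressure adds the resistive
drop of the instantaneous net flow:

    P_aw = P_alv + R · Q_net        (Q_net in L/s, positive inward)

Integration is explicit fixed-step (forward Euler) at the controller
sampling period, so plant and controller share one clock as in the
sampled-data device.  Configurations with dt > τ/5 (τ = R·C time
constant) are rejected upstream by the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import ConfigurationError, slpm_to_ml_per_s

__all__ = ["LungParams", "LungState", "lung_step", "passive_expiration_pressure"]


@dataclass(frozen=True)
class LungParams:
    """Test-lung mechanics.

    resistance : mbar/(L·s); the selectable levels 5/20/50/200 reproduce
        the commercial test lung but any positive value is accepted.
    compliance : mL/mbar; selectable levels 10/15/20/30.
    capacity   : mL, maximum inflation above resting volume (default 1 L).
    """

    resistance: float
    compliance: float
    capacity: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.resistance > 0 and self.compliance > 0 and self.capacity > 0):
            raise ConfigurationError(
                "lung resistance, compliance and capacity must all be positive, got "
                f"R={self.resistance}, C={self.compliance}, capacity={self.capacity}"
            )

    @property
    def time_constant(self) -> float:
        """Intrinsic RC time constant in seconds (R·C with C in L/mbar)."""
        return self.resistance * self.compliance / 1000.0


@dataclass(frozen=True)
class LungState:
    """Instantaneous lung state.

    volume            : mL above resting volume, clamped to [0, capacity].
    alveolar_pressure : mbar, = volume / compliance.
    airway_pressure   : mbar, alveolar plus resistive drop of net inflow.
    over_inflated     : set when an update tried to exceed capacity.
    """

    volume: float = 0.0
    alveolar_pressure: float = 0.0
    airway_pressure: float = 0.0
    over_inflated: bool = False


def lung_step(
    state: LungState,
    params: LungParams,
    inflow_slpm: float,
    outflow_slpm: float,
    dt: float,
) -> LungState:
    """Advance the compartment one explicit Euler step.

    Parameters
    ----------
    inflow_slpm, outflow_slpm
        Non-negative unidirectional flows in SLPM.
    dt
        Step in seconds (> 0).

    Volume hitting capacity clamps and raises the ``over_inflated`` flag
    on the returned state rather than erroring, so a sweep can report an
    unsafe configuration instead of crashing.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    net_ml_s = slpm_to_ml_per_s(inflow_slpm) - slpm_to_ml_per_s(outflow_slpm)
    raw = state.volume + net_ml_s * dt
    volume = min(max(raw, 0.0), params.capacity)
    alv = volume / params.compliance
    # resistive drop uses net flow in L/s
    aw = alv + params.resistance * net_ml_s / 1000.0
    return LungState(
        volume=volume,
        alveolar_pressure=alv,
        airway_pressure=aw,
        over_inflated=state.over_inflated or raw > params.capacity,
    )


def passive_expiration_pressure(
    t: float, pip: float, peep: float, r_total: float, c: float
) -> float:
    """Closed-form airway pressure during passive expiration (analytic oracle).

    A compartment of compliance ``c`` (mL/mbar) emptying from ``pip`` toward
    ``peep`` (mbar) through a total expiratory resistance ``r_total``
    (mbar/(L·s)) relaxes exponentially with τ = r_total·c/1000 seconds:

        P(t) = PEEP + (PIP − PEEP)·exp(−t/τ)
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if not (r_total > 0 and c > 0):
        raise ConfigurationError("r_total and c must be positive")
    tau = r_total * c / 1000.0
    return peep + (pip - peep) * math.exp(-t / tau)
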