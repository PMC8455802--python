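"""Sensor models and tidal-volume computation.

The device carries three sensors — inspiratory flow (0–100 SLPM span),
airway pressure, and oxygen fraction.  Each is modeled as an ideal
transducer with range clipping and optional additive Gaussian noise
(default off: no noise figures are published, so noise is opt-in for
robustness studies).  Tidal volume is the trapezoidal integral of the
*sensed* flow over the controller's inspiratory window, mirroring the
real device — sensor saturation therefore visibly biases V_T, which is
documented behavior, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import ConfigurationError

__all__ = [
    "SensorSpec",
    "SensorReading",
    "FLOW_SENSOR",
    "PRESSURE_SENSOR",
    "O2_SENSOR",
    "sensor_read",
    "integrate_tidal_volume",
]


@dataclass(frozen=True)
class SensorSpec:
    """Measurement range [lo, hi] and additive noise s.d. (same units as
    the measured quantity)."""

    lo: float
    hi: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError(f"sensor range requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be non-negative, got {self.noise_sd}")


# Inspiratory flow sensor span: 0–100 SLPM.
FLOW_SENSOR = SensorSpec(lo=0.0, hi=100.0)
# Airway pressure transducer; span comfortably covers the 0–2 psi drive band.
PRESSURE_SENSOR = SensorSpec(lo=0.0, hi=200.0)
# Zirconia oxygen sensor reads the full fraction range.
O2_SENSOR = SensorSpec(lo=0.0, hi=1.0)


@dataclass(frozen=True)
class SensorReading:
    time: float
    value: float
    saturated: bool


def sensor_read(
    true_value: float,
    spec: SensorSpec,
    rng: np.random.Generator | None = None,
    time: float = 0.0,
) -> SensorReading:
    """One sampled reading: clip(true + N(0, noise_sd), lo, hi).

    The ``saturated`` flag reflects the pre-noise true value falling
    outside the span.  With ``noise_sd = 0`` sensing is the identity
    inside range (bit-reproducible); with a seeded ``rng`` the noise
    sequence is reproducible.
    """
    saturated = not (spec.lo <= true_value <= spec.hi)
    value = true_value
    if spec.noise_sd > 0:
        if rng is None:
            raise ConfigurationError("noisy sensor requires an explicit rng")
        value += rng.normal(0.0, spec.noise_sd)
    value = min(max(value, spec.lo), spec.hi)
    return SensorReading(time=time, value=value, saturated=saturated)


def integrate_tidal_volume(
    flow_samples: Sequence[tuple[float, float]] | np.ndarray,
    phase_window: tuple[float, float] | None = None,
) -> float:
    """Tidal volume in mL from uniformly sampled flow (SLPM).

    ``flow_samples`` is a sequence of (time s, flow SLPM) pairs; the
    optional ``phase_window`` (t_start, t_end) restricts integration to
    the controller-logged inspiratory phase (the controller owns phase
    truth — phases are never re-detected from the waveform).  Uses the
    trapezoidal rule, O(dt²) accurate on smooth flows.
    """
    arr = np.asarray(flow_samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("flow_samples must be a sequence of (time, flow) pairs")
    t, q = arr[:, 0], arr[:, 1]
    if phase_window is not None:
        t0, t1 = phase_window
        mask = (t >= t0) & (t <= t1)
        t, q = t[mask], q[mask]
    if t.size < 2:
        raise ValueError("no inspiratory phase detected: window holds fewer than two samples")
    liters = np.trapezoid(q, t) / 60.0  # SLPM·s → L
    return float(liters * 1000.0)
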