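# Methods

## Model structure

The simulator is a sampled-data loop binding four submodels on one
clock (default 200 Hz):

1. **Controller** — a finite-state machine over {INSPIRATION,
   EXPIRATION}. Phase durations come from RR and I/E
   (`t_cycle = 60/RR`, `t_insp = t_cycle·(I/E)/(1+I/E)`) and are held as
   integer sample counts, so the breath period is exact and free of
   floating-point drift. Thresholds act only within a phase: pressure
   control closes the inspiratory solenoid when sensed lung pressure
   reaches PIP (by default a bang-bang *hold* that re-opens below the
   threshold; a single-shot variant is available via `pip_hold=False`),
   and the expiratory solenoid vents until pressure reaches PEEP, then
   holds. Volume control integrates the sensed flow (rectangle rule on
   the sampled readings) and closes at the V_T setpoint for the rest of
   the phase. Ties trip the threshold (≥/≤), which is deterministic and
   conservative toward lower pressures. Expiratory time and PEEP remain
   coupled, as in the physical device.
2. **Pneumatics** — relieving regulator (`min(supply, setpoint)`,
   setpoint constrained to 0–2 psi), needle valve with laminar
   conductance `A²/(8πµL)`, two binary solenoids, and a fixed linear
   expiratory resistance to ambient.
3. **Lung** — single R–C compartment, forward-Euler volume update,
   linear volume-independent compliance, volume clamped to
   [0, capacity] with an over-inflation flag instead of an exception so
   sweeps can report unsafe configurations.
4. **Sensors** — range clipping plus optional seeded Gaussian noise
   (default off: no transducer noise figures are available). The
   saturation flag reflects the pre-noise truth.

Update order per sample: controller (acting on the *previous* sample's
readings — one sample of loop latency, mirroring a real sampled system
and making the order unambiguous) → path flows → lung step → sensor
reads. With a fixed seed the whole record is bit-reproducible.

## Numerical choices

**Series-resistance flow solution.** Airway pressure depends
algebraically on the instantaneous flow (`P_aw = P_alv + R·Q`), so the
per-sample flows are solved exactly from the series pressure balance —
inspiration `Q = G(P_drive − P_alv)/(1 + G·R_lung)` with G the valve
conductance; expiration `Q = P_alv/(R_lung + R_exp)` — rather than
feeding the previous sample's airway pressure back into the valve law.
The delayed-feedback alternative diverges whenever lung resistance
exceeds the path resistance (e.g. the 200 mbar/(L·s) test-lung level),
while the balance solution is exact at every sample and leaves only the
volume integration explicit.

**Stability guard.** Forward Euler on the volume state is stable for
`dt < 2τ`; the engine rejects configurations with `dt > τ/5` (τ the
fastest phase's RC constant) to keep discretization error small, not
just bounded.

**Sensing point.** The pressure transducer is modeled as reading the
*lung* (compartment) pressure — the quantity PIP/PEEP gating is meant
to regulate. Gating instead on mouth pressure, which carries the
resistive drop R·Q, would make the bang-bang hold chatter from the
first sample of each breath and overshoot PIP by ~R·Q. The waveform
logs both signals (`pressure_*` sensed, `airway_pressure_mbar` true
mouth pressure).

**Gating granularity.** All threshold actions quantize to one sample.
Consequences, all verified by the test suite: PIP overshoot
≤ max_inflow·dt/C; end-expiratory pressure within one venting sample's
decrement of PEEP; delivered V_T within one sample of peak flow
(≈ 8.3 mL at 100 SLPM and 200 Hz) of the setpoint.

**Tidal volume** is the trapezoidal integral of the *sensed* (clipped)
flow over the controller-logged inspiratory window — saturation and
sensor noise therefore bias V_T exactly as they would on the device.
Phases are never re-detected from the waveform; the controller's log is
the truth.

## Default parameters

| parameter | default | why |
|---|---|---|
| sample rate | 200 Hz | the device's loop rate; >100 Hz advised, enforced |
| supply pressure | 50 psi | wall air/oxygen lines |
| regulator setpoint | 2 psi | top of the regulator band |
| valve orifice | calibrated | full-open flow = 100 SLPM (sensor span) at 2 psi into an empty lung; physical orifice dimensions are unpublished, so this is a documented calibration, overridable |
| expiratory resistance | 5 mbar/(L·s) | tubing + solenoid lump; unpublished, chosen so passive expiration at mid-range mechanics completes within a clinical expiratory phase |
| lung capacity | 1000 mL | the 1 L test lung |
| sensor noise | 0 | no published figures; opt-in |
| in vivo scenario | PIP 14 mmHg, PEEP 2 mmHg, RR 12 bpm, I/E 2.0, FiO₂ 40 %, R 10, C 30 | PEEP/FiO₂ are protocol values; PIP/RR/I/E fixed mid-range of the reported operating bands; lung mechanics are fixture choices, not measurements |

I/E ratios > 1 (inspiration longer than expiration) are accepted
literally as `t_insp:t_exp` and flagged with a warning, since the
reported in vivo range inverts clinical convention and guessing intent
would be worse than flagging.

## What the benchmark harness emulates — and does not

`run_matrix` reproduces the functional-test protocol: the Cartesian
product of four resistance levels, four compliance levels, two guidance
tidal volumes and three rates (96 conditions), each run to steady state
(six breaths, first dropped) in volume-control mode with PEEP 0 and
FiO₂ 0.21 (neither was specified independently in the protocol); a
pressure-mode sweep (quasi-static PIP = V_T/C) is available.  Guidance
pass/fail thresholds ship empty and are user configuration, because the
authoritative numeric limits live in a separate guidance document.

A green sweep establishes that the *control logic* meets its setpoints
on an idealized linear plant.  It does not establish anything about
real-gas effects (compressibility, humidity, BTPS corrections), tubing
compliance and dead space, nonlinear or volume-dependent lung
compliance (the physical test lung quotes compliance at 400 mL V_T),
solenoid actuation transients, sensor dynamics, or any gas-exchange
physiology — none of which are modeled.  High-resistance, high-rate
conditions legitimately under-deliver because the expiratory time
constant exceeds the cycle; the harness reports these as shortfalls
rather than failures of the sweep.

## Known limitations

- Single compartment, constant compliance, incompressible flow: the
  waveform morphology is ideal-plant, sharper than hardware traces.
- The one-sample loop latency is the only controller latency modeled;
  solenoid opening transients are instantaneous (switching error is
  bounded by one sampling period regardless).
- FiO₂ is a static blend recomputed per scenario, not a servo loop —
  matching the device, where oxygen titration is manual valve setting.
- The in vivo scenario validates controller behavior, not physiology:
  blood-gas outcomes are out of scope by design.
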