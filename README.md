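# ventsim

A deterministic, closed-loop simulator of a pneumatic emergency
ventilator — a device driven directly by compressed air and oxygen
lines, with two solenoid valves gated by sensor thresholds — coupled to
a single-compartment artificial test lung.  It is written for
respiratory-device engineers and control researchers who want to
exercise and verify this class of control logic entirely in software:
every subsystem of the gas path, the sensors, and the sampled control
law is modeled, and the standard 96-condition functional benchmark can
be re-run in seconds.

## The model

**Pneumatics.** Wall supplies (~50 psi) pass through relieving pressure
regulators into the 0–2 psi band, then through needle valves obeying the
laminar Hagen–Poiseuille law

```
Q = Δp · A² / (8π µ L)
```

(Q flow, Δp gradient across the valve, A orifice area, µ gas viscosity,
L restriction length).  Air (21 % O₂) and oxygen (100 %) flows mix
flow-weighted to set FiO₂ anywhere in 21–100 %.  Two binary solenoids
enforce one-way inspiratory/expiratory flow; the expiratory limb is a
fixed linear resistance to ambient.

**Lung.** A single R–C compartment: alveolar pressure `P = V/C`, airway
pressure `P_aw = P + R·Q_net`, with the selectable test-lung levels
R ∈ {5, 20, 50, 200} mbar/(L·s), C ∈ {10, 15, 20, 30} mL/mbar, 1 L
capacity.

**Control.** A 200 Hz sampled finite-state machine.  Breath timing is
clock-driven from RR and I/E; within a phase the solenoids are
bang-bang threshold-gated on the sensed lung pressure (pressure control:
close at PIP, vent to PEEP then hold) or on the integrated sensed flow
(volume control: close at the V_T setpoint).  Sensors clip to their
spans (flow: 0–100 SLPM) and can add seeded Gaussian noise.

As the lung inflates the pressure gradient across the valve collapses,
so inspiratory flow decays within each breath — the device's operating
principle, visible in every simulated waveform.

## Worked example

```python
from ventsim import sheep_scenario, simulate, breath_metrics

record = simulate(sheep_scenario(duration=30.0, seed=1))
print(breath_metrics(record).round(3).head(3).to_string(index=False))
```

```
 breath_index  max_insp_flow_slpm  mean_insp_flow_slpm  delivered_vt_ml  achieved_pip_mmhg  achieved_peep_mmhg  measured_rr_bpm  measured_ie  over_inflated
            0              89.217               10.091          557.183             14.024               1.985             12.0        2.003        False
            1              87.505                8.752          482.831             14.148               1.980             12.0        2.003        False
            2              87.509                8.753          482.853             14.143               1.979             12.0        2.003        False
```

Each row is one completed breath of the in vivo configuration (PIP
14 mmHg, PEEP 2 mmHg, RR 12 bpm, I/E 2, FiO₂ 40 %).  Achieved PIP and
PEEP sit within one 5 ms gating sample of their setpoints (14.14 vs 14,
1.98 vs 2 mmHg); the measured rate is exactly the set 12 bpm because
thresholds gate only within phases and never alter the clock.  The
first breath starts from an empty lung and is dropped from steady-state
summaries.

The `examples/` directory holds one short script per capability:
needle-valve flow and the regulator (`01`), FiO₂ blending (`02`), the
closed-loop in vivo scenario (`03`), volume-control delivery (`04`),
and the full 96-condition benchmark with guidance pass/fail checking
(`05`).  Scenarios can also be described in unit-tagged YAML
(`ventsim.config.load_scenario`); every dimensional quantity carries an
explicit unit (`peep: {value: 2, unit: mmHg}`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the blender endpoints (pure air / pure oxygen,
as percentages), the steady-state delivered tidal volume in
volume-control mode at the guidance-document maximum (750 mL,
high-compliance lung) and minimum (50 mL, low-compliance lung)
setpoints, and the flow sensor's saturation ceiling, and writes them as
JSON.
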