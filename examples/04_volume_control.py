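"""Volume-control mode: V_T gating at the guidance-document setpoints.

The controller integrates the sensed inspiratory flow and closes the
inspiratory solenoid once the delivered volume reaches the setpoint, so
the delivered V_T tracks the target to within one sample of flow.
"""

from ventsim import LungParams, Mode, Scenario, VentSettings, breath_metrics, psi, simulate

for vt, compliance, rr, label in [
    (750.0, 30.0, 6.0, "guidance maximum V_T, high-compliance lung"),
    (50.0, 10.0, 20.0, "guidance minimum V_T, low-compliance lung"),
]:
    settings = VentSettings(
        mode=Mode.VOLUME, vt_setpoint=vt, rr=rr, ie_ratio=1.0, pip=psi(2.0), peep=0.0
    )
    scenario = Scenario(
        settings=settings,
        lung=LungParams(resistance=5.0, compliance=compliance),
        duration=6 * 60.0 / rr,
        seed=1,
    )
    metrics = breath_metrics(simulate(scenario))
    steady = metrics[metrics["breath_index"] > 0]
    delivered = steady["delivered_vt_ml"].mean()
    sample_ml = 100.0 / 60.0 * 1000.0 * settings.dt
    print(f"{label}:")
    print(
        f"  target {vt:6.0f} mL -> delivered {delivered:7.1f} mL "
        f"(gating granularity: one 5 ms sample of peak flow = {sample_ml:.1f} mL)"
    )
print("\nthe residual error is the one-sample latency of threshold gating at")
print("200 Hz — the discretization floor of the sampled control loop.")
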