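"""Laminar needle-valve flow and the relieving pressure regulator.

Builds the default inspiratory valve — calibrated so that a 2 psi drive
into an empty lung gives the flow sensor's full 100 SLPM span — and
shows how flow scales with the pressure gradient and orifice area.
"""

from ventsim import (
    GasSupply,
    NeedleValveGeometry,
    RegulatorSetting,
    poiseuille_flow,
    psi,
    regulator_output,
)

supply = GasSupply(pressure=psi(50.0))           # ~50 psi wall line
regulator = RegulatorSetting(output_setpoint=psi(2.0))
drive = regulator_output(supply, regulator)
print(f"supply {supply.pressure:8.1f} mbar  ->  regulated drive {drive:7.2f} mbar")
print("(a relieving regulator caps its output at the setpoint, here 2 psi)")

valve = NeedleValveGeometry.for_max_flow(max_flow_slpm=100.0, drive_pressure=drive)
print(f"\ncalibrated orifice area: {valve.orifice_area:.3e} m^2 "
      f"(equivalent resistance {valve.equivalent_resistance:.1f} mbar/(L*s))")

print("\n  dp (mbar)   Q (SLPM)")
for frac in (1.0, 0.75, 0.5, 0.25, 0.0):
    dp = frac * drive
    print(f"  {dp:9.2f}  {poiseuille_flow(dp, valve):9.2f}")
print("flow is linear in the gradient: as the lung inflates the gradient")
print("collapses and inspiratory flow falls — the device's operating principle.")

half_area = NeedleValveGeometry(
    orifice_area=valve.orifice_area / 2,
    tube_length=valve.tube_length,
    dynamic_viscosity=valve.dynamic_viscosity,
)
print(f"\nhalving the orifice area quarters the flow: "
      f"{poiseuille_flow(drive, half_area):.2f} SLPM at full gradient (Q ~ A^2)")
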