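"""Gas path: regulator contract, laminar valve law, blending, solenoid flows."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventsim import (
    ConfigurationError,
    GasSupply,
    NeedleValveGeometry,
    RegulatorSetting,
    SolenoidState,
    blend_fio2,
    path_flow,
    poiseuille_flow,
    psi,
    regulator_output,
)


class TestRegulator:
    def test_relieves_high_supply_to_setpoint(self):
        out = regulator_output(GasSupply(pressure=psi(50.0)), RegulatorSetting(psi(2.0)))
        assert out == pytest.approx(psi(2.0))

    def test_cannot_exceed_supply(self):
        out = regulator_output(GasSupply(pressure=psi(1.0)), RegulatorSetting(psi(2.0)))
        assert out == pytest.approx(psi(1.0))

    def test_closed_regulator_delivers_nothing(self):
        assert regulator_output(GasSupply(), RegulatorSetting(0.0)) == 0.0

    def test_setpoint_band_enforced(self):
        with pytest.raises(ConfigurationError):
            RegulatorSetting(psi(3.0))
        with pytest.raises(ConfigurationError):
            RegulatorSetting(-1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        supply=st.floats(1.0, 5000.0),
        setpoint=st.floats(0.0, 137.8952),
    )
    def test_output_never_exceeds_setpoint(self, supply, setpoint):
        out = regulator_output(GasSupply(pressure=supply), RegulatorSetting(setpoint))
        assert out <= setpoint + 1e-12


class TestPoiseuille:
    GEOM = NeedleValveGeometry(
        orifice_area=math.pi * (2e-3) ** 2, tube_length=0.5, dynamic_viscosity=1.81e-5
    )

    def test_zero_gradient_zero_flow(self):
        assert poiseuille_flow(0.0, self.GEOM) == 0.0

    def test_negative_gradient_blocked(self):
        assert poiseuille_flow(-10.0, self.GEOM) == 0.0

    def test_hand_evaluated_oracle(self):
        """Independent arithmetic of Q = Δp·A²/(8πµL) for a 2 mm-radius
        orifice, L = 0.5 m, µ = 1.81e-5 Pa·s at Δp = 1 psi."""
        dp_pa = 68.9476 * 100.0
        area = math.pi * (2e-3) ** 2
        q_m3s = dp_pa * area**2 / (8.0 * math.pi * 1.81e-5 * 0.5)
        expected_slpm = q_m3s * 60000.0
        assert poiseuille_flow(psi(1.0), self.GEOM) == pytest.approx(expected_slpm, rel=1e-12)

    def test_quadratic_in_area(self):
        doubled = NeedleValveGeometry(
            orifice_area=2 * self.GEOM.orifice_area,
            tube_length=self.GEOM.tube_length,
            dynamic_viscosity=self.GEOM.dynamic_viscosity,
        )
        q1 = poiseuille_flow(10.0, self.GEOM)
        q2 = poiseuille_flow(10.0, doubled)
        assert q2 == pytest.approx(4.0 * q1, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(dp=st.floats(1e-3, 200.0), scale=st.floats(0.5, 5.0))
    def test_linear_in_pressure_drop(self, dp, scale):
        q1 = poiseuille_flow(dp, self.GEOM)
        q2 = poiseuille_flow(scale * dp, self.GEOM)
        assert q2 == pytest.approx(scale * q1, rel=1e-9)

    def test_calibrated_geometry_hits_sensor_span(self):
        geom = NeedleValveGeometry.for_max_flow(max_flow_slpm=100.0, drive_pressure=psi(2.0))
        assert poiseuille_flow(psi(2.0), geom) == pytest.approx(100.0, rel=1e-9)


class TestBlend:
    def test_pure_air_endpoint(self):
        assert blend_fio2(10.0, 0.0) == pytest.approx(0.21)

    def test_pure_oxygen_endpoint(self):
        assert blend_fio2(0.0, 10.0) == pytest.approx(1.0)

    def test_equal_flows_midpoint(self):
        assert blend_fio2(5.0, 5.0) == pytest.approx(0.605)

    def test_undefined_mixture(self):
        with pytest.raises(ConfigurationError):
            blend_fio2(0.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        air=st.floats(0.0, 100.0),
        o2_lo=st.floats(0.0, 100.0),
        bump=st.floats(0.0, 50.0),
    )
    def test_monotone_and_bounded(self, air, o2_lo, bump):
        if air + o2_lo == 0:
            o2_lo = 1e-6
        f_lo = blend_fio2(air, o2_lo)
        f_hi = blend_fio2(air, o2_lo + bump)
        assert 0.21 <= f_lo <= 1.0
        assert f_hi >= f_lo - 1e-12


class TestPathFlow:
    GEOM = NeedleValveGeometry.for_max_flow()

    def kwargs(self, **over):
        base = dict(
            drive_pressure=psi(2.0),
            alveolar_pressure=0.0,
            lung_resistance=5.0,
            geom=self.GEOM,
            expiratory_resistance=5.0,
        )
        base.update(over)
        return base

    def test_breath_hold_no_flow(self):
        assert path_flow(SolenoidState(False, False), **self.kwargs()) == (0.0, 0.0)

    def test_equilibrated_gradient_no_inflow(self):
        inflow, _ = path_flow(
            SolenoidState(inspiratory_open=True), **self.kwargs(alveolar_pressure=psi(2.0))
        )
        assert inflow == 0.0

    def test_inflow_decreases_as_lung_fills(self):
        flows = [
            path_flow(SolenoidState(inspiratory_open=True), **self.kwargs(alveolar_pressure=p))[0]
            for p in (0.0, 20.0, 60.0, 120.0)
        ]
        assert all(a > b for a, b in zip(flows, flows[1:]))

    def test_unidirectional(self):
        inflow, outflow = path_flow(
            SolenoidState(True, False), **self.kwargs(alveolar_pressure=500.0)
        )
        assert inflow == 0.0 and outflow == 0.0
        _, outflow = path_flow(
            SolenoidState(False, True), **self.kwargs(alveolar_pressure=-1.0)
        )
        assert outflow == 0.0

    def test_expiratory_series_resistance(self):
        # lung R and expiratory path R act in series on the outflow
        _, outflow = path_flow(
            SolenoidState(False, True),
            **self.kwargs(alveolar_pressure=30.0, lung_resistance=10.0, expiratory_resistance=5.0),
        )
        assert outflow == pytest.approx(30.0 / 15.0 * 60.0)
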