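"""Closed-loop engine: determinism, waveform morphology, breath metrics."""

import numpy as np
import pandas as pd
import pytest

from ventsim import (
    ConfigurationError,
    LungParams,
    Mode,
    Phase,
    RegulatorSetting,
    Scenario,
    VentSettings,
    WAVEFORM_COLUMNS,
    breath_metrics,
    mmhg,
    psi,
    sheep_scenario,
    simulate,
)


def pressure_scenario(pip=30.0, peep=0.0, rr=20.0, r=5.0, c=20.0, duration=12.0, **over):
    settings = VentSettings(mode=Mode.PRESSURE, pip=pip, peep=peep, rr=rr, ie_ratio=1.0)
    return Scenario(
        settings=settings, lung=LungParams(r, c), duration=duration, seed=1, **over
    )


class TestSimulate:
    def test_zero_drive_pressure_is_flat(self):
        scen = pressure_scenario(regulator=RegulatorSetting(0.0))
        rec = simulate(scen)
        assert rec["pressure_mbar"].abs().max() == 0.0
        assert rec["flow_slpm"].abs().max() == 0.0
        assert rec["volume_ml"].abs().max() == 0.0

    def test_same_seed_bit_identical(self):
        a = simulate(sheep_scenario(duration=10.0, seed=3))
        b = simulate(sheep_scenario(duration=10.0, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_waveform_schema_and_clock(self):
        rec = simulate(pressure_scenario())
        assert list(rec.columns) == WAVEFORM_COLUMNS
        dt = np.diff(rec["time_s"].to_numpy())
        assert np.allclose(dt, 1.0 / 200.0)

    def test_solenoids_never_both_open(self):
        rec = simulate(sheep_scenario(duration=20.0, seed=1))
        assert not (rec["insp_valve"] & rec["exp_valve"]).any()

    def test_unstable_step_rejected(self):
        # tiny compliance → expiratory time constant shorter than 5 samples
        scen = pressure_scenario(c=1.0)
        with pytest.raises(ConfigurationError, match="unstable"):
            simulate(scen)

    def test_duration_below_one_cycle_rejected(self):
        with pytest.raises(ConfigurationError):
            pressure_scenario(rr=6.0, duration=5.0)

    def test_sheep_waveform_morphology(self):
        """The in vivo configuration shows a pressure plateau near PIP and a
        decaying inspiratory flow within each breath."""
        scen = sheep_scenario(duration=20.0, seed=1)
        rec = simulate(scen)
        breath = rec[(rec["breath_index"] == 2)]
        insp = breath[breath["phase"] == Phase.INSPIRATION.value]
        pip = scen.settings.pip
        # plateau: most of inspiration sits within 2% of the PIP setpoint
        plateau_frac = (np.abs(insp["pressure_mbar"] - pip) < 0.02 * pip).mean()
        assert plateau_frac > 0.5
        # decaying flow: non-increasing after its within-breath peak
        flow = insp["flow_slpm"].to_numpy()
        k = int(np.argmax(flow))
        assert np.all(np.diff(flow[k:]) <= 1e-9)

    def test_pip_overshoot_bounded_by_one_sample(self):
        scen = sheep_scenario(duration=20.0, seed=1)
        rec = simulate(scen)
        m = breath_metrics(rec)
        dt = scen.settings.dt
        max_inflow_mls = rec["flow_slpm"].max() * 1000.0 / 60.0
        bound_mbar = max_inflow_mls * dt / scen.lung.compliance
        overshoot = m["achieved_pip_mmhg"] * 1.33322 - scen.settings.pip  # mbar
        assert (overshoot <= bound_mbar + 1e-9).all()


class TestBreathMetrics:
    def test_rate_and_ie_follow_the_clock(self):
        scen = pressure_scenario(rr=20.0)
        m = breath_metrics(simulate(scen))
        assert np.allclose(m["measured_rr_bpm"], 20.0, atol=1e-9)
        assert np.allclose(m["measured_ie"], 1.0, atol=1e-9)

    def test_rate_holds_with_unreachable_pip(self):
        # drive far below PIP: thresholds never trip, timing must not deadlock
        scen = pressure_scenario(pip=psi(2.0), regulator=RegulatorSetting(psi(0.5)))
        m = breath_metrics(simulate(scen))
        assert len(m) >= 2
        assert np.allclose(m["measured_rr_bpm"], 20.0, atol=1e-9)

    def test_steady_state_periodicity(self):
        """After the start-up breath the linear loop has no drift: consecutive
        breath metrics agree to better than 0.5%."""
        m = breath_metrics(simulate(sheep_scenario(duration=30.0, seed=1)))
        steady = m[m["breath_index"] >= 3]
        for col in ["delivered_vt_ml", "achieved_pip_mmhg", "achieved_peep_mmhg", "max_insp_flow_slpm"]:
            vals = steady[col].to_numpy()
            assert np.all(np.abs(np.diff(vals)) < 0.005 * np.abs(vals[:-1]))

    def test_quasi_static_volume_matches_compliance_relation(self):
        """With inspiration ≫ the RC time constant, delivered V_T approaches
        (PIP − PEEP)·C (quasi-static limit), within 5%."""
        scen = pressure_scenario(pip=50.0, rr=6.0, c=10.0, duration=60.0)
        m = breath_metrics(simulate(scen))
        steady = m[m["breath_index"] > 0]
        expected = (scen.settings.pip - scen.settings.peep) * scen.lung.compliance
        assert steady["delivered_vt_ml"].mean() == pytest.approx(expected, rel=0.05)

    def test_delivered_vt_monotone_in_drive_and_compliance(self):
        """In the flow-limited regime (PIP unreachable) delivered volume
        strictly increases with drive pressure and with compliance."""
        def vt(drive_psi, c):
            scen = pressure_scenario(
                pip=psi(2.0), c=c, regulator=RegulatorSetting(psi(drive_psi))
            )
            m = breath_metrics(simulate(scen))
            return m[m["breath_index"] > 0]["delivered_vt_ml"].mean()

        by_drive = [vt(d, 20.0) for d in (0.5, 1.0, 1.5, 1.9)]
        assert all(a < b for a, b in zip(by_drive, by_drive[1:]))
        by_c = [vt(1.0, c) for c in (10.0, 15.0, 20.0, 30.0)]
        assert all(a < b for a, b in zip(by_c, by_c[1:]))

    def test_max_flow_bounds_mean_flow(self):
        m = breath_metrics(simulate(sheep_scenario(duration=20.0, seed=1)))
        assert (m["max_insp_flow_slpm"] >= m["mean_insp_flow_slpm"]).all()
        assert (m["mean_insp_flow_slpm"] >= 0).all()

    def test_no_completed_breath_warns_and_returns_empty(self):
        rec = simulate(pressure_scenario(rr=6.0, duration=10.0))  # one breath only
        one_breath = rec[rec["breath_index"] == 0]
        with pytest.warns(UserWarning):
            m = breath_metrics(one_breath)
        assert m.empty
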