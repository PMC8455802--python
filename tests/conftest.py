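import pytest

from ventsim import LungParams, Mode, Scenario, VentSettings, psi


def volume_scenario(vt, compliance, rr, resistance=5.0, seed=1, n_breaths=6, **over):
    """Volume-control scenario on a test-lung setting, 2 psi drive, defaults."""
    settings = VentSettings(
        mode=Mode.VOLUME,
        vt_setpoint=vt,
        rr=rr,
        ie_ratio=1.0,
        pip=psi(2.0),
        peep=0.0,
    )
    return Scenario(
        settings=settings,
        lung=LungParams(resistance=resistance, compliance=compliance),
        duration=n_breaths * 60.0 / rr,
        seed=seed,
        **over,
    )


@pytest.fixture
def make_volume_scenario():
    return volume_scenario
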