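import numpy as np
import pytest

from circuq import model


@pytest.fixture(scope="session")
def default_cfg():
    return model.default_config()


@pytest.fixture(scope="session")
def settled_cfg():
    """Longer warm-up so the Windkessel transient is fully decayed."""
    return model.default_config(n_beats=10, n_discard=6)


@pytest.fixture(scope="session")
def default_result(default_cfg):
    return model.simulate(default_cfg)


@pytest.fixture(scope="session")
def default_qois(default_cfg, default_result):
    return model.extract_qois(default_result, default_cfg)


class ConstantVolume:
    """Degenerate waveform used to freeze the ventricle in tests."""

    def __init__(self, volume, HR=60.0):
        self._v = volume
        self.mode = model.BeatingMode(HR=HR, ESV=volume, EDV=2 * volume)

    def volume(self, t):
        return self._v

    def dvolume(self, t):
        return 0.0


@pytest.fixture
def frozen_ventricle_cfg():
    """Clamped pump, zero atrial pressure, rigid ventricle: a dead rig."""
    cfg = model.default_config(pump=0, P_LA=0.0,
                               wk=model.Windkessel3E(Pc=0.0))
    object.__setattr__(cfg, "waveform", ConstantVolume(180e-6))
    return cfg
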