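import numpy as np
import pytest

from lfpcascade import SimConfig, synth


@pytest.fixture(scope="session")
def short_cfg():
    """Small-but-spectrally-resolvable default configuration."""
    return SimConfig(duration=20.0, seed=11)


@pytest.fixture(scope="session")
def sawtooth_pair():
    """(channel, phase) for a 30 s asymmetric theta trace."""
    cfg = SimConfig(duration=30.0, seed=3, asymmetry=0.6)
    return synth.gen_sawtooth_theta(cfg)


@pytest.fixture(scope="session")
def bursting_trains():
    """20 bursting units plus 2 injected 40 Hz control units, 120 s."""
    cfg = SimConfig(duration=120.0, seed=21)
    return synth.gen_spike_trains(cfg, n_units=20,
                                  regime_params={"n_control": 2}, seed=21)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
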