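import numpy as np
import pytest

from dlam import synth


@pytest.fixture(scope="session")
def quiet_session():
    """Noise-free single-condition laminar session at 1 kHz (exact forward model)."""
    params = synth.SessionParams(
        fs=1000.0, n_blocks_per_condition=1, block_s=30.0, interblock_s=10.0,
        conditions=("monocular",), pink_noise_v=0.0, line_noise_v=0.0)
    session, schedule, truth = synth.generate_session(params, seed=11)
    return params, session, schedule, truth


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise single-condition session, 100 trials."""
    params = synth.SessionParams(
        fs=1000.0, n_blocks_per_condition=1, block_s=100.0, interblock_s=10.0,
        conditions=("monocular",))
    session, schedule, truth = synth.generate_session(params, seed=21)
    return params, session, schedule, truth


@pytest.fixture(scope="session")
def four_condition_spikes():
    """Spike trains for all four conditions with the default effect gains."""
    params = synth.SessionParams(
        fs=1000.0, n_blocks_per_condition=1, block_s=120.0, interblock_s=10.0)
    schedule = synth.generate_schedule(params, np.random.default_rng(3))
    truth = synth.GroundTruth(3, 32, 28, {}, params.early_gain, params.late_gain)
    units, truth = synth.generate_units(
        synth.UnitParams(n_units=20), schedule, truth, seed=3)
    return params, schedule, units, truth
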