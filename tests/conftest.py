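import numpy as np
import pytest

import scratchdetect as sd


@pytest.fixture(scope="session")
def sim_config():
    return sd.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def three_bout_schedule():
    return sd.make_schedule(600, 3, (12, 30), rng_seed=11)


@pytest.fixture(scope="session")
def rendered_video(three_bout_schedule, sim_config):
    return sd.render_video(three_bout_schedule, sim_config)


@pytest.fixture(scope="session")
def small_pre_config():
    return sd.PreprocessConfig(out_size=64)


@pytest.fixture(scope="session")
def segment_dataset(rendered_video, small_pre_config):
    seq, track = rendered_video
    return sd.build_segments(seq, track, small_pre_config)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest legal architecture; fast enough for shape/gradient tests."""
    return sd.CRNNSpec(conv_channels=(2, 3, 4), lstm_units=(5, 4),
                       fc_units=(6, 5, 4, 3, 1), input_size=8, seq_len=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return sd.build(tiny_spec, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
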