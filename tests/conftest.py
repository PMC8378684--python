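import pytest

from winterdisp.environment import make_environment
from winterdisp.synthetic import SimulationConfig, simulate_tag_records, simulate_tracks


@pytest.fixture(scope="session")
def env():
    return make_environment()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def tracks(env, default_config):
    return simulate_tracks(default_config, env)


@pytest.fixture(scope="session")
def track_and_records(env, default_config, tracks):
    track = tracks[0]
    records = simulate_tag_records(track, env, default_config)
    return track, records


@pytest.fixture(scope="session")
def noise_free_track_and_records(env):
    config = SimulationConfig(twilight_noise_sd=0.0, sst_noise_sd=0.0)
    track = simulate_tracks(config, env)[0]
    records = simulate_tag_records(track, env, config)
    return config, track, records
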