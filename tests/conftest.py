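import numpy as np
import pytest

from semg2angle import SimConfig, preprocess, sim
from semg2angle.windows import WindowSpec, concat_trials, make_windows


@pytest.fixture(scope="session")
def gait_cfg() -> SimConfig:
    return SimConfig.for_pattern("gait", seed=7)


@pytest.fixture(scope="session")
def gait_session(gait_cfg):
    return sim.simulate_session(gait_cfg)


@pytest.fixture(scope="session")
def gait_trial(gait_session):
    raw, _ = gait_session
    return preprocess.preprocess_session(raw)


@pytest.fixture(scope="session")
def gait_windows(gait_trial):
    return make_windows(gait_trial, WindowSpec())


@pytest.fixture(scope="session")
def multi_trial_windows():
    """Five short, fast gait trials expanded into one window set."""
    cfg = SimConfig(pattern="gait", duration_s=4.0, seed=21)
    sets = []
    for i, (raw, _) in enumerate(sim.simulate_trials(cfg, 5)):
        sets.append(make_windows(preprocess.preprocess_session(raw), trial_id=i))
    return concat_trials(sets)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
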