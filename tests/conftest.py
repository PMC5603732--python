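import numpy as np
import pytest

from wheeltask import ObserverParams, TaskConfig, generate_session

#: 11-condition detection contrast set used throughout the recovery tests.
CONTRASTS_11 = (0.0, 0.06, 0.12, 0.25, 0.5, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ObserverParams(b_left=-0.5, b_right=0.3, s_left=5.0,
                          s_right=6.0, c50=0.15, n=2.0)


@pytest.fixture
def auc2_session(default_params):
    cfg = TaskConfig(variant="auc2_detection", n_trials=2000,
                     contrast_set=CONTRASTS_11)
    return generate_session(cfg, default_params, rng=7)


@pytest.fixture
def afc2_session():
    params = ObserverParams(0.0, 0.2, 4.0, 4.0, 0.15, 2.0)
    cfg = TaskConfig(variant="afc2_detection", n_trials=2000)
    return generate_session(cfg, params, rng=11)
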