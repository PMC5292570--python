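import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from myobench.config import default_config
from myobench.pipeline import TrainParams
from myobench.config import SessionSpec

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size bench config for fast classifier tests."""
    cfg = default_config(seed=7)
    return dataclasses.replace(
        cfg,
        session=SessionSpec(train_s=3.0, test_reps=1, test_s=2.0),
        train=TrainParams(epochs=300),
    )


@pytest.fixture(scope="session")
def trained_small(small_cfg):
    from myobench.bench import train_classifier

    return train_classifier(small_cfg, "ppy", 1234)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
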