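import numpy as np
import pytest

from sagloc import (
    Direction,
    ListenerModel,
    ModelConfig,
    Predictor,
    SyntheticListenerParams,
    generate_listener_dtfs,
)


@pytest.fixture(scope="session")
def listener_dtf():
    """One deterministic virtual listener on the default grids."""
    return generate_listener_dtfs(SyntheticListenerParams(seed=1), listener_id="VL01")


@pytest.fixture(scope="session")
def flat_dtf():
    """A cue-free listener: every direction shares one spectrum per ear."""
    return generate_listener_dtfs(
        SyntheticListenerParams(cue_quality=0.0, seed=1), listener_id="FLAT"
    )


@pytest.fixture(scope="session")
def predictor(listener_dtf):
    return Predictor(listener_dtf, config=ModelConfig())


@pytest.fixture(scope="session")
def targets(listener_dtf):
    return [d for d in listener_dtf.directions if abs(d.lateral) <= 30.0]


@pytest.fixture(scope="session")
def listener(listener_dtf):
    return ListenerModel(dtf=listener_dtf, uncertainty=2.0, ground_truth_U=2.0)


@pytest.fixture(scope="session")
def small_group():
    """Three calibrated virtual listeners with distinct uncertainties."""
    group = []
    for i, u in enumerate((1.5, 2.0, 2.6)):
        dtf = generate_listener_dtfs(
            SyntheticListenerParams(cue_quality=1.0 - 0.1 * i, seed=50 + i),
            listener_id=f"VL{i + 1:02d}",
        )
        group.append(ListenerModel(dtf=dtf, uncertainty=u, ground_truth_U=u))
    return group


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
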