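import numpy as np
import pytest

import cxcompass as cx
from cxcompass import network as net
from cxcompass.model import HeadingModel, ModelConfig
from cxcompass.plasticity import OfflineFitSpec

# Explicit lasso penalty (the per-sample scale cross-validation settles on)
# keeps the suite fast; the CV default is exercised separately.
FAST_LAMBDA = 2 * 6000 * 100.0


@pytest.fixture(scope="session")
def layout():
    return net.build_layout()


@pytest.fixture(scope="session")
def connectome(layout):
    return net.build_connectome(layout)


@pytest.fixture(scope="session")
def lif_params():
    return net.LIFParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rotation_model():
    """Short rotation trial shared by integration tests."""
    world = cx.default_rotation_world()
    traj = cx.default_rotation_trajectory(duration=10.0)
    cfg = ModelConfig(offline=OfflineFitSpec(lambda_=FAST_LAMBDA))
    return HeadingModel(world, traj, cfg)


@pytest.fixture(scope="session")
def optimal_results(rotation_model):
    return rotation_model.fit(configuration="optimal", seed=7, n_seeds=2)
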