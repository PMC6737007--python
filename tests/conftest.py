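import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compliant_pose():
    from vsdkit import synthetic

    pose, truth = synthetic.gen_toy_complex(None, seed=1)
    return pose


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
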