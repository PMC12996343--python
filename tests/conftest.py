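import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pepsim as pp

settings.register_profile(
    "pepsim",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pepsim")


@pytest.fixture(scope="session")
def porcine_printed():
    return pp.builtin_model("porcine", "as_printed")


@pytest.fixture(scope="session")
def human_corrected():
    return pp.builtin_model("human", "corrected")


@pytest.fixture(scope="session")
def human_printed():
    return pp.builtin_model("human", "as_printed")


@pytest.fixture(scope="session")
def paper_like_design_pts():
    from pepsim.synthetic import paper_like_design

    return paper_like_design(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
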