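import numpy as np
import pytest

from mempattern import (
    DesignConfig,
    SignalConfig,
    default_roi_specs,
    generate_roi_masks,
    generate_trial_design,
)
from mempattern._svm import warmup


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the numba kernels once up front so timings are predictable."""
    warmup()


@pytest.fixture(scope="session")
def demo_masks():
    return generate_roi_masks((20, 20, 20), default_roi_specs())


@pytest.fixture(scope="session")
def hc_mask(demo_masks):
    return demo_masks[0]


@pytest.fixture(scope="session")
def ec_mask(demo_masks):
    return demo_masks[1]


@pytest.fixture(scope="session")
def study_design():
    """The default 21-cued + 30-free trial design."""
    return generate_trial_design(DesignConfig(seed=1))


@pytest.fixture(scope="session")
def strong_signal_cfg():
    return SignalConfig(effect_size=3.0, seed=1)


@pytest.fixture(scope="session")
def null_signal_cfg():
    return SignalConfig(effect_size=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
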