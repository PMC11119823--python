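import numpy as np
import pytest

from hopflow.experiments import run_trajectory_demo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trajectory_demo():
    """Shared d=5, N=4 demo including the fully trained denoiser.

    Training the 750-unit MLP for 5000 iterations dominates the cost, so
    the demo is computed once per session and reused by the denoiser and
    experiment tests.
    """
    return run_trajectory_demo(seed=3, n_steps=2000)
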