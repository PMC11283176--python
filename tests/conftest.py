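import numpy as np
import pytest

from bvsim import FitConfig, generate_sim1
from bvsim.ecm import _fit_fixed_k, _lmm_init


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_data():
    """A small skewed-design dataset shared across tests."""
    data, truth = generate_sim1(30, seed=42)
    return data, truth


@pytest.fixture(scope="session")
def quick_config():
    """Estimation settings for cheap test fits."""
    return FitConfig(max_iter=150, tol_param=1e-4, n_interior=2,
                     init="ols", newton_max=2)


@pytest.fixture(scope="session")
def small_fit(small_data, quick_config):
    """One converged-ish fit on the small dataset, reused by several tests."""
    data, _ = small_data
    return _fit_fixed_k(data, quick_config, 2,
                        init_core=_lmm_init(data, "ols"))
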