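import numpy as np
import pytest

import connspace as cs


@pytest.fixture(scope="session")
def small_gradient():
    """Small noiseless gradient fixture (n=60, m=600) with ground truth."""
    return cs.generate_graded_profiles(60, 600, noise_sd=0.0, rng_seed=1)


@pytest.fixture(scope="session")
def small_gradient_noisy():
    return cs.generate_graded_profiles(60, 600, noise_sd=0.05, rng_seed=1)


@pytest.fixture(scope="session")
def study_gradient():
    """Study-scale noisy gradient (n=200, m=2000)."""
    return cs.generate_graded_profiles(200, 2000, noise_sd=0.05, rng_seed=7)


@pytest.fixture()
def random_profiles():
    """Strictly positive random profiles -> fully connected similarity graph."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.1, 1.0, size=(20, 50))
    coords = np.column_stack([np.arange(20), np.zeros(20), np.zeros(20)])
    return cs.ProfileSet(values, coords)
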