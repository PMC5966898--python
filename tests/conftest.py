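import warnings

import pytest

from omicspatterns import SimConfig, generate_time_course

# the factorization warns when a restart hits its iteration cap; that is
# expected on small noisy problems and irrelevant to the assertions here
warnings.filterwarnings("ignore", message=".*iteration cap.*")


@pytest.fixture(scope="session")
def sim_default():
    """Default-noise two-arm time course, 600 genes."""
    return generate_time_course(SimConfig(n_genes=600, seed=11))


@pytest.fixture(scope="session")
def sim_noiseless():
    """Noiseless planted dataset, 400 genes."""
    return generate_time_course(SimConfig(n_genes=400, seed=7, noise_scale=0.0))
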