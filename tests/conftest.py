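import numpy as np
import pytest

from fddm.environment import EnvironmentSpec, Fixed, Gaussian
from fddm.experiments import preset_environment
from fddm.mvt import solve_environment

# The intermediate study environment: A = 5, T_tr = 5, s = 1, E* = 2,
# for which the self-consistent initial patch density is rho0 = 9.439.
A_MED, TTR_MED, S_MED, ESTAR_MED = 5.0, 5.0, 1.0, 2.0


@pytest.fixture(scope="session")
def medium_sol():
    return solve_environment(A_MED, TTR_MED, S_MED, E_star=ESTAR_MED)


@pytest.fixture(scope="session")
def medium_env():
    """Fixed-parameter medium environment with continuous reward."""
    return preset_environment(ESTAR_MED, TTR_MED, A_MED)


@pytest.fixture(scope="session")
def medium_env_chunks():
    """Medium environment with discrete chunks of size 8."""
    return preset_environment(ESTAR_MED, TTR_MED, A_MED, c=8.0)


@pytest.fixture(scope="session")
def uncertain_density_env(medium_sol):
    """Patch quality uncertain: Gaussian rho0 with sd 0.3 * mean, fixed travel."""
    return EnvironmentSpec(
        rho0_dist=Gaussian(medium_sol.rho0, 0.3 * medium_sol.rho0),
        A_dist=Fixed(A_MED),
        c=0.0,
        Ttr_dist=Fixed(TTR_MED),
        s=S_MED,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
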