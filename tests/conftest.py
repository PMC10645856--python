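import numpy as np
import pytest

import rrtvar as rv

MEANS = (3.0, 3.0, 3.0)
N_LARGE = 100_000


@pytest.fixture(scope="session")
def pop1():
    """Benchmark population I (sigma_y^2 = 10, rho ~ 0.67)."""
    return rv.generate_population(rv.POPULATION_I_COV, MEANS, N_LARGE, seed=101)


@pytest.fixture(scope="session")
def pop2():
    """Benchmark population II (sigma_y^2 = 6, rho ~ 0.87)."""
    return rv.generate_population(rv.POPULATION_II_COV, MEANS, N_LARGE, seed=202)


@pytest.fixture(scope="session")
def dp_params():
    return rv.DPModelParams(var_s=0.5, var_t=0.5)


@pytest.fixture(scope="session")
def np_params():
    return rv.NPModelParams(g=0.5, a=1.0, var_r=0.5, var_s=0.5, mode="consistent")


@pytest.fixture(scope="session")
def dp_moments(pop1, dp_params):
    z = rv.scramble_dp(pop1.y_values, dp_params, seed=11)
    return rv.compute_population_moments(pop1, z)


@pytest.fixture(scope="session")
def np_moments(pop1, np_params):
    z = rv.scramble_proposed(pop1.y_values, np_params, seed=12)
    return rv.compute_population_moments(pop1, z)


@pytest.fixture(scope="session")
def dp_moments2(pop2, dp_params):
    z = rv.scramble_dp(pop2.y_values, dp_params, seed=13)
    return rv.compute_population_moments(pop2, z)


@pytest.fixture
def tiny_pop():
    rng = np.random.default_rng(5)
    return rv.FinitePopulation(rng.normal(3, 2, 40), rng.normal(3, 1, 40),
                               rng.normal(3, 1, 40))
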