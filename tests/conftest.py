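import numpy as np
import pytest

from signalgap import ModelParams, QualityDist, solve_equilibrium


@pytest.fixture(scope="session")
def unit_params() -> ModelParams:
    """Scale-set reference parameters lambda = sigma = beta = 1 on q in [0, 5]."""
    return ModelParams()


@pytest.fixture(scope="session")
def unit_solution(unit_params):
    return solve_equilibrium(unit_params)


@pytest.fixture(scope="session")
def unit_quality_dist(unit_params) -> QualityDist:
    return QualityDist.from_params(unit_params)


@pytest.fixture(scope="session")
def long_range_solution():
    """Unit-parameter equilibrium solved deep into the asymptotic tail."""
    p = ModelParams(q_max=35.0)
    return solve_equilibrium(p, np.linspace(0.0, 35.0, 3001))
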