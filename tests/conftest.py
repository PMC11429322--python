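import numpy as np
import pytest

from meropk.model_core import PKParameters, Regimen
from meropk.population import CovariateDistribution, PopulationModel, sample_population


@pytest.fixture(scope="session")
def typical():
    """The typical-subject parameter set of the final model."""
    return PKParameters(CL=12.4, V1=8.26, Q=5.22, V2=4.06)


@pytest.fixture(scope="session")
def standard_regimen():
    return Regimen(dose=500.0, infusion_duration=0.5, interval=8.0)


@pytest.fixture(scope="session")
def small_population():
    """A modest shared virtual population for PTA unit tests."""
    return sample_population(PopulationModel(), CovariateDistribution(), 2000, seed=123)


def random_parameter_sets(n, seed=0):
    """Physiologically plausible random two-compartment parameter sets."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            PKParameters(
                CL=float(np.exp(rng.uniform(np.log(3.0), np.log(30.0)))),
                V1=float(np.exp(rng.uniform(np.log(3.0), np.log(20.0)))),
                Q=float(np.exp(rng.uniform(np.log(1.0), np.log(15.0)))),
                V2=float(np.exp(rng.uniform(np.log(2.0), np.log(15.0)))),
            )
        )
    return out
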