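import numpy as np
import pytest

from minkin import KineticParameters, ModelId, generate_curve


@pytest.fixture
def sfo_params():
    return KineticParameters(model_id=ModelId.SFO, k1=0.02, m_max=40.0)


@pytest.fixture
def hs_params():
    return KineticParameters(model_id=ModelId.HS, k1=0.03, k2=5e-4, tb=12.0)


@pytest.fixture
def fomc_params():
    return KineticParameters(model_id=ModelId.FOMC, alpha=2.0, beta=64.4)


@pytest.fixture
def noisefree_sfo_curve(sfo_params):
    return generate_curve(sfo_params, noise_sd=0.0, seed=0)


def random_params(rng: np.random.Generator, model_id: ModelId) -> KineticParameters:
    """Random valid parameter draw spanning realistic soil kinetics."""
    m_max = rng.uniform(5.0, 100.0)
    if model_id is ModelId.SFO:
        return KineticParameters(
            model_id=model_id, k1=10.0 ** rng.uniform(-4, -1), m_max=m_max
        )
    if model_id is ModelId.FOMC:
        return KineticParameters(
            model_id=model_id,
            alpha=10.0 ** rng.uniform(-1.2, 1.0),
            beta=10.0 ** rng.uniform(-1, 2.5),
            m_max=m_max,
        )
    return KineticParameters(
        model_id=model_id,
        k1=10.0 ** rng.uniform(-3, -1),
        k2=10.0 ** rng.uniform(-4, -2),
        tb=rng.uniform(2.0, 40.0),
        m_max=m_max,
    )
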