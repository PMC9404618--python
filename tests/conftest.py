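import numpy as np
import pytest

import krtbayes as kb


@pytest.fixture(scope="session")
def thresholds():
    return kb.build_thresholds()


@pytest.fixture(scope="session")
def fast_sampler():
    """Short chains for structural tests; too short for the convergence gate."""
    return kb.SamplerConfig(chains=2, warmup_draws=300,
                            kept_draws_per_chain=300, seed=42)


@pytest.fixture(scope="session")
def small_trial():
    """600-patient, 12-site synthetic trial with a null treatment effect."""
    return kb.generate_trial(kb.SimulationConfig(
        n_patients=600, n_sites=12, seed=7))


@pytest.fixture(scope="session")
def margins_data():
    """Deterministic dataset matching the published per-arm death counts."""
    from krtbayes.synthetic_trial import from_margins
    return from_margins(643, 1465, 639, 1462)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
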