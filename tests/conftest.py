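import numpy as np
import pytest

from admixscan import syndata


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic data set shared across tests."""
    cfg = syndata.SimConfig(
        seed=11, n_sites=2000, cohort_size=120,
        sweeps=[syndata.Sweep(site=1000, target=0.95, ancestral=0.2)],
        phenotype=syndata.PhenotypeModel(risk_site=1000, beta=0.5),
    )
    return cfg, syndata.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
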