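import numpy as np
import pytest

from prenylflux.correction import mean_enrichment
from prenylflux.pathway import default_pathway
from prenylflux.simulate import strain_config, simulate_labeling


@pytest.fixture(scope="session")
def pathway():
    return default_pathway()


@pytest.fixture(scope="session")
def wt_noiseless_states(pathway):
    """Noise-free wild-type labeling trajectory on the standard grid."""
    config = strain_config("WT", pathway=pathway, noise_cv=0.0, replicates=1)
    return config, simulate_labeling(config)


@pytest.fixture(scope="session")
def wt_enrichment_curves(wt_noiseless_states):
    """time grid + per-pool noise-free enrichment arrays."""
    config, states = wt_noiseless_states
    times = np.array([s.time_min for s in states])
    curves = {
        pool.name: np.array([mean_enrichment(s.distributions[pool.name]) for s in states])
        for pool in config.pathway.quantifiable_pools
    }
    return times, curves
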