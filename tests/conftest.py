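import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20101118)


@pytest.fixture
def small_sim_config():
    """A desk-scale synthetic library: 5 true candidates, 3 of each decoy."""
    from aphidmine.simulate import LibrarySimConfig
    return LibrarySimConfig(
        seed=1, n_true_candidates=5, n_tm_decoys=3, n_nonsecreted_decoys=3,
        n_monomorphic_decoys=3, n_background_salivary=10, n_background_all=15,
        n_background_gut=8)
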