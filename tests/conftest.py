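import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20_120_119)


@pytest.fixture
def small_pair():
    """A small indel-free paralog pair at 8% divergence with flanks."""
    from nahrkit.simdata import SimConfig, make_paralogs
    cfg = SimConfig(ancestor_length=1200, flank_length=300,
                    indel_rate=0.0, seed=3)
    return make_paralogs(cfg)
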