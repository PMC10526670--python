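import numpy as np
import pytest

from cerna_screen import SimulationConfig, simulate_bundle
from cerna_screen.io import concat_count_matrices

# strong planted effects: the regime the end-to-end recovery criterion targets
STRONG_EFFECTS = dict(beta=1.0, target_rho=0.8, n_reps=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic bundle reused by tests that only need a valid one."""
    cfg = SimulationConfig(seed=11, **STRONG_EFFECTS)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle_counts(small_bundle):
    return concat_count_matrices(
        small_bundle.counts_case, small_bundle.counts_ctrl
    )
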