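import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import hyconn as hc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 subjects, 10 regions — fast end-to-end plumbing checks."""
    spec = hc.CohortSpec(
        n_patients=10, n_controls=10, n_regions=10, n_timepoints=60,
        base_correlation=hc.BlockModel(n_blocks=2, within=0.5, between=0.1),
        perturbations=((0, 5, 0.4), (1, 6, 0.4)),
        noise_sd=0.2, seed=7,
    )
    return hc.generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_cohort():
    return hc.generate_cohort(hc.separable_scenario(11))


def random_symmetric(rng, n, zero_diag=True):
    M = rng.normal(size=(n, n))
    M = (M + M.T) / 2
    if zero_diag:
        np.fill_diagonal(M, 0.0)
    return M
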