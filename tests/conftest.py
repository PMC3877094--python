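import numpy as np
import pytest

from ifnsig import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across tests (seed fixed)."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_config():
    """Miniature cohort config for fast structural tests."""
    return SimulationConfig(
        n_common=6, n_disease_specific=5, n_immunisation_specific=2,
        n_non_ifn_de=3, n_null=12, n_absent=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def brute_force_signed_rank_p(diffs, mu=0.0):
    """Independent oracle: enumerate all sign assignments of the non-zero
    differences and count null statistics at least as large as observed."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.5
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n
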