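import logging

import numpy as np
import pytest

import stemcycle as sc
from stemcycle.simulate import example_trajectory_specs, simulate_trajectory

# Marker-list warnings from intentionally reduced fixtures are noise here.
logging.getLogger("stemcycle.cellcycle").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def trajectory_profile():
    """Seeded synthetic neurogenic-trajectory profile (140 cells)."""
    return simulate_trajectory(example_trajectory_specs(), n_cells=140, seed=11)


@pytest.fixture
def tiny_profile():
    """3 cells x 2 genes with hand-checkable CPM values."""
    return sc.make_profile([[0.0, 0.0], [3.0, 1.0], [7.0, 1.0]],
                           ["c1", "c2", "c3"], ["g1", "g2"], [0.0, 0.5, 1.0])


def brute_force_fisher_p(table):
    """Independent two-sided Fisher oracle: enumerate every table with
    the observed margins and sum hypergeometric probabilities not
    exceeding the observed table's."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(xs, n, r1, c1)
    p_obs = pmf[xs == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-10)].sum()))
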