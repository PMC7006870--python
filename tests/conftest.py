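import numpy as np
import pytest

from froinet import CohortSpec, canonical_hrf, default_design, make_regressor
from froinet.cohort import CORE_FROIS, DEFAULT_CATALOG


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def kernel(design):
    return canonical_hrf(design.tr_seconds)


@pytest.fixture(scope="session")
def regressor(design, kernel):
    return make_regressor(design, kernel)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort (~90 voxels/subject) for fast end-to-end tests."""
    catalog = tuple(
        (name, (8, 12)) if name in CORE_FROIS else (name, (6, 10))
        for name, _ in DEFAULT_CATALOG
    )
    return CohortSpec(froi_catalog=catalog, n_subjects=5, seed=42)


def random_simple_graph(rng: np.random.Generator, n_max: int):
    """A random G(n, p) simple graph with n in [2, n_max]."""
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.9))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
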