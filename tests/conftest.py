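import numpy as np
import pytest

from striacell.matrix_io import ClusterAssignment, CountMatrix
from striacell.synthetic_data import CountSimConfig, GradientSpec, simulate_counts


@pytest.fixture(scope="session")
def small_reference():
    """7-cluster study-shaped reference matrix with truth (session-scoped:
    simulated once, read-only in tests)."""
    cfg = CountSimConfig(seed=123, gradient=GradientSpec(cluster="C1"))
    return simulate_counts(cfg)


@pytest.fixture()
def tiny_matrix():
    """The 3x2 matrix {{1,0},{0,2},{5,5}} used by the I/O examples."""
    return CountMatrix(
        counts=np.array([[1, 0], [0, 2], [5, 5]]),
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["cA", "cB"],
    )


@pytest.fixture()
def two_cluster_assignment():
    return ClusterAssignment({"cA": "X", "cB": "Y"})
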