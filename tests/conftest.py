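import numpy as np
import pytest

from sddam import make_label_volume, voxel_proportions


@pytest.fixture(scope="session")
def small_atlas():
    """30-region synthetic atlas on a 48^3 grid at 2 mm spacing."""
    return make_label_volume(30, shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0), seed=7)


@pytest.fixture(scope="session")
def small_expectations(small_atlas):
    return voxel_proportions(small_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def scale_graph_from_adjacency(adj, scale=10.0):
    """Build a ScaleGraph directly from a 0/1 adjacency matrix."""
    from sddam.graphs import ScaleGraph

    adj = np.asarray(adj, dtype=np.int8)
    ids = tuple(str(i) for i in range(adj.shape[0]))
    return ScaleGraph(scale=scale, node_ids=ids, adjacency=adj)
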