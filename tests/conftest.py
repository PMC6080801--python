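import networkx as nx
import numpy as np
import pytest

import ductnet as dn


@pytest.fixture(scope="session")
def fixtures():
    return dn.make_fixtures()


@pytest.fixture(scope="session")
def plexus320():
    """One growth-model plexus at the best-fit parameters."""
    return dn.grow_network(dn.GrowthParams(
        lambda_mean=0.25, delta_pool=1, n_target=320, seed=11,
    ))


@pytest.fixture(scope="session")
def small_plexus():
    return dn.grow_network(dn.GrowthParams(
        lambda_mean=0.25, delta_pool=1, n_target=60, seed=5,
    ))


@pytest.fixture(scope="session")
def unit_chain200():
    n = 200
    return dn.SpatialNetwork(
        node_ids=list(range(1, n + 1)),
        positions=[[float(i), 0.0, 0.0] for i in range(n)],
        edges=[(i, i + 1) for i in range(1, n)],
        root_id=1,
        name="chain200",
    )


@pytest.fixture(scope="session")
def grid20():
    g = nx.grid_2d_graph(20, 20)
    mapping = {node: i + 1 for i, node in enumerate(sorted(g.nodes))}
    return dn.SpatialNetwork(
        node_ids=list(mapping.values()),
        positions=[[float(x), float(y), 0.0] for (x, y) in sorted(g.nodes)],
        edges=[(mapping[u], mapping[v]) for u, v in g.edges],
        root_id=1,
        name="grid20",
    )


def random_connected_graph(n_nodes: int, seed: int) -> dn.SpatialNetwork:
    """Random connected simple graph with random 3D positions."""
    rng = np.random.default_rng(seed)
    while True:
        p = rng.uniform(0.15, 0.5)
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    pos = rng.uniform(0, 10, size=(n_nodes, 3))
    return dn.SpatialNetwork(
        node_ids=list(range(1, n_nodes + 1)),
        positions=pos,
        edges=[(u + 1, v + 1) for u, v in g.edges],
        root_id=1,
        name=f"rand_{seed}",
    )
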