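"""Stochastic growth model for plexus formation by redundant linking.

New lumen nodes nucleate near the existing network and immediately
connect to nearby nodes, producing the loop-rich plexus seen at the
early developmental stage.  One growth step:

1.  Propose a point uniformly in the ball of radius
    ``r_max = max(d_com) + 0.5`` around the network's centre of mass
    (``d_com`` = node distances to the centre of mass) and accept it
    with probability ``prod_i (1 - exp(-d_i))`` where ``d_i`` is its
    distance to existing node *i* — proposals landing on top of an
    existing lumen are rejected, so the kernel sets the length unit to
    roughly one inter-lumen spacing.
2.  Draw ``M ~ Poisson(lambda)`` and link the new node to ``M + 1``
    targets chosen uniformly without replacement from its
    ``M + 1 + Delta`` nearest existing nodes.  ``lambda`` controls
    redundancy (how many extra links), ``Delta`` the spatial
    sloppiness of where they attach.
3.  Repeat until the target node count is reached.

With ``lambda = 0, Delta = 0`` every node makes exactly one most-local
link and the result is a tree; ``lambda = 0.25, Delta = 1`` is the
regime that best reproduces early-plexus statistics.

The acceptance probability is implemented with the decaying exponent
``1 - exp(-d_i)`` (the only form that is a probability and penalises
proximity); growth is in 3D by default, with a planar mode for
comparison.  A single seeded generator drives all randomness in a fixed
order (acceptance sampling, Poisson draw, pool choice), so a run is
fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import SpatialNetwork, _canon

__all__ = [
    "GrowthParams",
    "propose_node_position",
    "attach_node",
    "grow_network",
    "random_lsystem",
]

#: retry budget for the rejection sampler of new node positions
ACCEPT_RETRY_BUDGET = 100_000


@dataclass
class GrowthParams:
    """Parameters of the plexus growth model.

    ``lambda_mean`` is the Poisson mean of extra links per new node,
    ``delta_pool`` the slack of the candidate pool beyond the links to
    place, ``n_target`` the final node count.  ``init_mode`` seeds the
    model either with two nodes joined by a unit edge or with a small
    random binary (dichotomic) tree of ``l_system_size`` nodes.
    """

    lambda_mean: float = 0.25
    delta_pool: int = 1
    n_target: int = 320
    init_mode: str = "two_nodes"
    l_system_size: int = 4
    planar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_mean < 0:
            raise ValueError("lambda_mean must be >= 0")
        if self.delta_pool < 0:
            raise ValueError("delta_pool must be >= 0")
        if self.n_target < 2:
            raise ValueError("n_target must be >= 2")
        if self.init_mode not in ("two_nodes", "l_system"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


def _uniform_ball(rng: np.random.Generator, center: np.ndarray,
                  radius: float, planar: bool) -> np.ndarray:
    if planar:
        v = rng.normal(size=2)
        v /= np.linalg.norm(v)
        r = radius * np.sqrt(rng.uniform())
        return center + np.array([v[0] * r, v[1] * r, 0.0])
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return center + v * r


def acceptance_probability(point: np.ndarray, positions: np.ndarray) -> float:
    """``prod_i (1 - exp(-d_i))`` over existing nodes i."""
    d = np.linalg.norm(positions - point, axis=1)
    return float(np.prod(-np.expm1(-d)))


def propose_node_position(
    positions: np.ndarray,
    rng: np.random.Generator,
    planar: bool = False,
    retry_budget: int = ACCEPT_RETRY_BUDGET,
) -> np.ndarray:
    """Rejection-sample a new lumen position near the existing cloud.

    Uniform proposal in the ball of radius ``max(d_com) + 0.5`` about
    the centre of mass, thinned by the proximity-penalising acceptance
    kernel.  Raises ``RuntimeError`` if no proposal is accepted within
    the retry budget (degenerate geometry, e.g. a collapsed cloud).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    com = positions.mean(axis=0)
    r_max = float(np.max(np.linalg.norm(positions - com, axis=1))) + 0.5
    for _ in range(retry_budget):
        p = _uniform_ball(rng, com, r_max, planar)
        if rng.uniform() < acceptance_probability(p, positions):
            return p
    raise RuntimeError(
        f"no proposal accepted in {retry_budget} tries "
        "(degenerate node geometry?)"
    )


def attach_node(
    net: SpatialNetwork,
    point: np.ndarray,
    params: GrowthParams,
    rng: np.random.Generator,
    new_id: int | None = None,
) -> SpatialNetwork:
    """Add a node at ``point`` with ``M + 1`` links, ``M ~ Poisson(lambda)``.

    Targets are drawn uniformly without replacement from the
    ``M + 1 + Delta`` nearest existing nodes; both the link count and
    the pool are capped at the existing network size.
    """
    m = int(rng.poisson(params.lambda_mean))
    n_exist = net.n_nodes
    n_links = min(m + 1, n_exist)
    pool_size = min(m + 1 + params.delta_pool, n_exist)
    d = np.linalg.norm(net.positions - np.asarray(point), axis=1)
    # stable nearest-first ordering; ties broken by node index
    pool_idx = np.argsort(d, kind="stable")[:pool_size]
    chosen = rng.choice(pool_idx, size=n_links, replace=False)
    if new_id is None:
        new_id = max(net.node_ids) + 1
    node_ids = net.node_ids + [new_id]
    positions = np.vstack([net.positions, np.asarray(point, dtype=float)])
    edges = list(net.edges)
    lengths = dict(net.edge_lengths)
    for i in sorted(int(c) for c in chosen):
        e = _canon(net.node_ids[i], new_id)
        edges.append(e)
        lengths[e] = float(d[i])
    return SpatialNetwork(
        node_ids=node_ids,
        positions=positions,
        edges=edges,
        edge_lengths=lengths,
        root_id=net.root_id,
        name=net.name,
    )


def random_lsystem(
    n_init: int,
    rng: np.random.Generator,
    planar: bool = False,
    branch_length: float = 1.0,
) -> SpatialNetwork:
    """Spatially random binary (dichotomic) tree of ``n_init`` nodes.

    Starting from a single node, tips iteratively spawn two children at
    ``branch_length`` mean distance in random directions, until the tree
    has ``n_init`` nodes (the last tip may spawn a single child to hit
    the count exactly).  Connected and acyclic by construction.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    ids = [1]
    positions = [np.zeros(3)]
    edges: list[tuple[int, int]] = []
    tips = [0]
    while len(ids) < n_init:
        parent = tips.pop(0)
        for _ in range(min(2, n_init - len(ids))):
            direction = rng.normal(size=2 if planar else 3)
            direction /= np.linalg.norm(direction)
            if planar:
                direction = np.array([direction[0], direction[1], 0.0])
            length = branch_length * rng.uniform(0.5, 1.5)
            positions.append(positions[parent] + direction * length)
            ids.append(len(ids) + 1)
            child = len(ids) - 1
            edges.append((ids[parent], ids[child]))
            tips.append(child)
    return SpatialNetwork(
        node_ids=ids,
        positions=np.vstack(positions),
        edges=edges,
        root_id=1,
        name=f"lsystem_{n_init}",
    )


def grow_network(
    params: GrowthParams,
    return_audit: bool = False,
) -> SpatialNetwork:
    """Grow a plexus to ``params.n_target`` nodes.

    The root is the first initial node.  With ``return_audit`` the
    per-step link counts are returned alongside the network, for
    book-keeping checks (total edges = initial edges + sum(1 + M)).
    """
    rng = np.random.default_rng(params.seed)
    if params.init_mode == "two_nodes":
        net = SpatialNetwork(
            node_ids=[1, 2],
            positions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            edges=[(1, 2)],
            root_id=1,
            name="plexus",
        )
    else:
        net = random_lsystem(params.l_system_size, rng, planar=params.planar)
    audit: list[int] = []
    while net.n_nodes < params.n_target:
        before = net.n_edges
        p = propose_node_position(net.positions, rng, planar=params.planar)
        net = attach_node(net, p, params, rng)
        audit.append(net.n_edges - before)
    net.name = (
        f"plexus_lam{params.lambda_mean}_delta{params.delta_pool}"
        f"_n{params.n_target}_seed{params.seed}"
    )
    if return_audit:
        return net, audit
    return net
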