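"""Network statistics for staged duct networks.

Computes the per-sample statistic vector used to characterise each
developmental stage: node/edge counts, total duct length ``L_tot``,
degree distribution, mean clustering, simple-cycle (polygon) counts of
length 3-5 from adjacency-matrix traces, cost and performance relative
to the Euclidean minimum spanning tree, mean network distances to the
root and between all node pairs, and the network's scaling dimension.
Also provides degree-preserving randomised counterparts and two-sample
group comparisons with Bonferroni correction.

Notation
--------
For a simple undirected graph with adjacency matrix ``A``, degree
``d_i`` and edge count ``|E|``, the numbers of triangles, squares and
pentagons are

.. math::

    n(C_3) &= \\tfrac{1}{6}\\,\\mathrm{tr}(A^3) \\\\
    n(C_4) &= \\tfrac{1}{8}\\bigl[\\mathrm{tr}(A^4)
              - 4\\textstyle\\sum_i \\binom{d_i}{2} - 2|E|\\bigr] \\\\
    n(C_5) &= \\tfrac{1}{10}\\bigl[\\mathrm{tr}(A^5)
              - 5\\textstyle\\sum_i A^3_{ii}(d_i - 2) - 30\\,n(C_3)\\bigr]

Cost is ``C = L_tot / L_tot^MST`` (>= 1; redundancy of the wiring) and
performance ``P = <l> / <l_MST>`` where ``<l>`` averages weighted
shortest-path lengths over all ordered node pairs (self-pairs included,
i.e. an N^2 normalisation); P < 1 means the extra links shorten
transport paths relative to the minimal spanning wiring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io_core import SpatialNetwork, _canon, to_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSummary",
    "GroupComparison",
    "degree_distribution",
    "count_polygons",
    "mean_clustering",
    "euclidean_mst",
    "cost",
    "performance",
    "mean_distances",
    "network_dimension",
    "randomize_degree_preserving",
    "summarize",
    "compare_groups",
]

#: dimension estimation: sample at most this many source nodes
DIMENSION_MAX_SOURCES = 500
#: dimension fit window: cumulative count between this floor and N/2
DIMENSION_COUNT_FLOOR = 5
#: default number of attempted double-edge swaps per edge
RANDOMIZE_SWAPS_PER_EDGE = 10


@dataclass
class NetworkSummary:
    """Per-network statistic vector (one row of the stage comparison)."""

    n_nodes: int
    n_edges: int
    total_length: float
    mean_degree: float
    mean_clustering: float
    n_triangles: int
    n_squares: int
    n_pentagons: int
    cost: float
    performance: float
    mean_dist_root: float
    mean_pairwise_dist: float
    root_ratio: float
    dimension: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroupComparison:
    """Two-sample comparison of one summary measure between groups."""

    measure: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    bonferroni_alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.bonferroni_alpha


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def degree_distribution(net: SpatialNetwork) -> dict[int, int]:
    """Map degree -> node count; degree-1 nodes are terminal ends."""
    counts: dict[int, int] = {}
    deg = dict.fromkeys(net.node_ids, 0)
    for u, v in net.edges:
        deg[u] += 1
        deg[v] += 1
    for d in deg.values():
        counts[d] = counts.get(d, 0) + 1
    return dict(sorted(counts.items()))


def count_polygons(net: SpatialNetwork) -> tuple[int, int, int]:
    """Counts of simple cycles of length 3, 4 and 5 (triangles, squares,
    pentagons) from powers of the binary adjacency matrix.

    The square count subtracts, per node, the ``C(d_i, 2)`` closed
    4-walks that bounce through two distinct neighbours, and the ``2|E|``
    back-and-forth walks; the pentagon count subtracts the closed
    5-walks that traverse a triangle plus a pendant step.
    """
    a, _ = to_adjacency(net)
    d = a.sum(axis=1)
    e = net.n_edges
    a2 = a @ a
    a3 = a2 @ a
    tr3 = np.trace(a3)
    tr4 = np.trace(a2 @ a2)
    tr5 = np.trace(a3 @ a2)
    n3 = tr3 / 6.0
    n4 = (tr4 - 4.0 * np.sum(d * (d - 1) / 2.0) - 2.0 * e) / 8.0
    n5 = (tr5 - 5.0 * np.sum(np.diag(a3) * (d - 2.0)) - 30.0 * n3) / 10.0
    return (int(round(n3)), int(round(n4)), int(round(n5)))


def mean_clustering(net: SpatialNetwork) -> float:
    """Average local clustering coefficient; degree < 2 contributes 0."""
    if net.n_nodes == 0:
        return 0.0
    return float(nx.average_clustering(net.to_networkx()))


# ---------------------------------------------------------------------------
# Euclidean MST, cost and performance
# ---------------------------------------------------------------------------

def _mst_edges_dense(positions: np.ndarray) -> list[tuple[int, int]]:
    dm = squareform(pdist(positions))
    # deterministic tie-break: perturb nothing, scipy's Prim order on the
    # dense matrix is reproducible for identical input
    tree = minimum_spanning_tree(sparse.csr_matrix(dm), overwrite=False)
    coo = tree.tocoo()
    return [(int(i), int(j)) for i, j in zip(coo.row, coo.col)]


def _mst_edges_knn(positions: np.ndarray, k: int = 15) -> list[tuple[int, int]]:
    from scipy.spatial import cKDTree

    n = len(positions)
    tree = cKDTree(positions)
    dist, idx = tree.query(positions, k=min(k + 1, n))
    rows, cols, vals = [], [], []
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            rows.append(i)
            cols.append(int(j))
            vals.append(float(d))
    g = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    g = g.maximum(g.T)
    ncomp, labels = sparse.csgraph.connected_components(g, directed=False)
    while ncomp > 1:
        # stitch components through their closest cross pair
        best = None
        for c in range(1, ncomp):
            ia = np.flatnonzero(labels == 0)
            ib = np.flatnonzero(labels == c)
            d = np.linalg.norm(
                positions[ia][:, None, :] - positions[ib][None, :, :], axis=-1
            )
            p, q = np.unravel_index(np.argmin(d), d.shape)
            cand = (d[p, q], int(ia[p]), int(ib[q]))
            if best is None or cand < best:
                best = cand
        g = g.tolil()
        g[best[1], best[2]] = g[best[2], best[1]] = best[0]
        g = g.tocsr()
        ncomp, labels = sparse.csgraph.connected_components(g, directed=False)
    mst = minimum_spanning_tree(g)
    coo = mst.tocoo()
    return [(int(i), int(j)) for i, j in zip(coo.row, coo.col)]


def euclidean_mst(net: SpatialNetwork, dense_limit: int = 2000) -> SpatialNetwork:
    """Euclidean minimum spanning tree on the node cloud.

    Built on the complete distance graph for up to ``dense_limit``
    nodes; above that on a 15-nearest-neighbour graph with a
    connectivity fallback.  Edge lengths are straight-line distances.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network has no spanning tree")
    if n == 1:
        return net.with_edges([], {})
    if n <= dense_limit:
        pairs = _mst_edges_dense(net.positions)
    else:
        pairs = _mst_edges_knn(net.positions)
    edges = []
    lengths = {}
    for i, j in pairs:
        u, v = net.node_ids[i], net.node_ids[j]
        e = _canon(u, v)
        edges.append(e)
        lengths[e] = net.euclidean_length(u, v)
    return net.with_edges(edges, lengths)


def _require_connected(net: SpatialNetwork, what: str) -> None:
    if not net.is_connected():
        raise ValueError(f"{what} requires a connected network")


def cost(net: SpatialNetwork) -> float:
    """Wiring cost C = L_tot / L_tot^MST (>= 1 for connected inputs)."""
    _require_connected(net, "cost")
    mst = euclidean_mst(net)
    return net.total_length / mst.total_length


def _weighted_sparse(net: SpatialNetwork) -> sparse.csr_matrix:
    n = net.n_nodes
    idx = net._id_to_index
    rows, cols, vals = [], [], []
    for (u, v), ln in net.edge_lengths.items():
        i, j = idx[u], idx[v]
        rows += [i, j]
        cols += [j, i]
        vals += [ln, ln]
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _all_pairs_mean(net: SpatialNetwork) -> float:
    """Mean weighted shortest-path length over all N^2 ordered pairs
    (self-pairs contribute 0)."""
    dm = dijkstra(_weighted_sparse(net), directed=False)
    if np.isinf(dm).any():
        raise ValueError("network is disconnected")
    return float(dm.sum()) / net.n_nodes**2


def performance(net: SpatialNetwork) -> float:
    """Transport performance P = <l> / <l_MST> (< 1 for loop-rich nets)."""
    _require_connected(net, "performance")
    mst = euclidean_mst(net)
    return _all_pairs_mean(net) / _all_pairs_mean(mst)


def mean_distances(net: SpatialNetwork) -> tuple[float, float, float]:
    """(<D_root>, <D>, <D_root>/<D>): mean weighted shortest-path
    distance of every node to the root (N normalisation, root included),
    mean over all ordered pairs (N^2 normalisation), and their ratio.
    """
    _require_connected(net, "mean_distances")
    w = _weighted_sparse(net)
    dm = dijkstra(w, directed=False)
    ri = net.index_of(net.root_id)
    d_root = float(dm[ri].sum()) / net.n_nodes
    d_all = float(dm.sum()) / net.n_nodes**2
    return d_root, d_all, d_root / d_all if d_all > 0 else float("nan")


# ---------------------------------------------------------------------------
# Network dimension
# ---------------------------------------------------------------------------

def network_dimension(
    net: SpatialNetwork,
    count_floor: int = DIMENSION_COUNT_FLOOR,
    count_ceiling_frac: float = 0.5,
    max_sources: int = DIMENSION_MAX_SOURCES,
    seed: int = 0,
    return_per_node: bool = False,
):
    """Scaling dimension of the network.

    For each sampled source node, the cumulative number of nodes within
    network distance ``r`` grows as ``r^dim``; the dimension is the mean
    over sources of the slope of ``log(count)`` vs ``log(r + l0)``,
    where ``l0`` is the median nearest-neighbour spacing.  The offset
    anchors the fit at the exact point count(0) = 1 (a radius-0 ball
    holds just the source), removing the small-radius discreteness bias
    of the bare ``log r`` fit; it cancels from the slope as radii grow
    and leaves the estimate invariant under global rescaling.  The fit
    window keeps radii where the count lies between ``count_floor``
    nodes (small-count noise) and ``count_ceiling_frac * N`` nodes
    (boundary saturation); a source with fewer than 3 usable points is
    skipped.  All nodes are used as sources when ``N <= max_sources``,
    otherwise a seeded random subset.
    """
    _require_connected(net, "network_dimension")
    n = net.n_nodes
    dm = dijkstra(_weighted_sparse(net), directed=False)
    rng = np.random.default_rng(seed)
    if n <= max_sources:
        sources = np.arange(n)
    else:
        sources = rng.choice(n, size=max_sources, replace=False)
    slopes = []
    ceiling = count_ceiling_frac * n
    # typical inter-node spacing: median over nodes of the nearest
    # positive network distance (= shortest incident edge)
    with np.errstate(invalid="ignore"):
        masked = np.where(dm > 0, dm, np.inf)
    l0 = float(np.median(masked.min(axis=1)))
    for s in sources:
        # cumulative histogram: nodes within distance r, one point per
        # distinct radius (ties collapse to their full cumulative count)
        r, last = np.unique(np.sort(dm[s]), return_index=True)
        counts = np.empty_like(r)
        counts[:-1] = last[1:].astype(float)
        counts[-1] = float(n)
        mask = (counts >= count_floor) & (counts <= ceiling) & (r > 0)
        if mask.sum() < 3:
            continue
        slope = np.polyfit(np.log(r[mask] + l0), np.log(counts[mask]), 1)[0]
        slopes.append(slope)
    if not slopes:
        raise ValueError(
            "dimension fit window selected < 3 points for every source node"
        )
    if return_per_node:
        return float(np.mean(slopes)), np.asarray(slopes)
    return float(np.mean(slopes))


# ---------------------------------------------------------------------------
# Degree-preserving randomisation
# ---------------------------------------------------------------------------

def randomize_degree_preserving(
    net: SpatialNetwork,
    n_swaps: int | None = None,
    seed: int = 0,
) -> SpatialNetwork:
    """Connected double-edge-swap randomisation.

    Attempts ``n_swaps`` (default 10 per edge) swaps; a swap replacing
    edges (a, b), (c, d) by (a, d), (c, b) is rejected if it would
    create a self-loop or multi-edge or disconnect the graph.  Node
    positions are untouched; new edge lengths are the Euclidean
    distances between the rewired endpoints.  The degree multiset and
    connectivity are invariant.
    """
    _require_connected(net, "randomize_degree_preserving")
    if n_swaps is None:
        n_swaps = RANDOMIZE_SWAPS_PER_EDGE * net.n_edges
    rng = np.random.default_rng(seed)
    g = net.to_networkx()
    edges = list(g.edges)
    done = 0
    for _ in range(n_swaps):
        if len(edges) < 2:
            break
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        if nx.is_connected(g):
            edges[i] = (a, d)
            edges[j] = (c, b)
            done += 1
        else:
            g.remove_edge(a, d)
            g.remove_edge(c, b)
            g.add_edge(a, b)
            g.add_edge(c, d)
    if done < n_swaps // 20 and net.n_edges > 3:
        warnings.warn(
            f"only {done} of {n_swaps} attempted swaps succeeded; "
            "randomisation may be incomplete",
            stacklevel=2,
        )
    logger.debug("double-edge swaps: %d/%d accepted", done, n_swaps)
    new_edges = [_canon(u, v) for u, v in g.edges]
    lengths = {e: net.euclidean_length(*e) for e in new_edges}
    return net.with_edges(new_edges, lengths)


# ---------------------------------------------------------------------------
# Summary & group comparison
# ---------------------------------------------------------------------------

def summarize(net: SpatialNetwork, dimension_seed: int = 0) -> NetworkSummary:
    """Full statistic vector for one network."""
    _require_connected(net, "summarize")
    n3, n4, n5 = count_polygons(net)
    mst = euclidean_mst(net)
    d_root, d_all, ratio = mean_distances(net)
    try:
        dim = network_dimension(net, seed=dimension_seed)
    except ValueError:
        dim = float("nan")
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        total_length=net.total_length,
        mean_degree=2.0 * net.n_edges / net.n_nodes,
        mean_clustering=mean_clustering(net),
        n_triangles=n3,
        n_squares=n4,
        n_pentagons=n5,
        cost=net.total_length / mst.total_length,
        performance=_all_pairs_mean(net) / _all_pairs_mean(mst),
        mean_dist_root=d_root,
        mean_pairwise_dist=d_all,
        root_ratio=ratio,
        dimension=dim,
    )


def compare_groups(
    summaries_a: list[NetworkSummary],
    summaries_b: list[NetworkSummary],
    alpha: float = 0.05,
    measures: list[str] | None = None,
    equal_var: bool = True,
) -> list[GroupComparison]:
    """Two-sample, two-tailed t tests per measure, Bonferroni-adjusted.

    ``bonferroni_alpha = alpha / (number of measures tested)``.  Both
    groups need >= 2 summaries.  Zero variance in both groups with equal
    means yields p = 1 by convention.
    """
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise ValueError("each group needs at least 2 summaries")
    if measures is None:
        measures = [f.name for f in fields(NetworkSummary)]
    adj = alpha / len(measures)
    out = []
    for m in measures:
        xa = np.array([getattr(s, m) for s in summaries_a], dtype=float)
        xb = np.array([getattr(s, m) for s in summaries_b], dtype=float)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            t = 0.0 if xa.mean() == xb.mean() else float("inf")
            p = 1.0 if xa.mean() == xb.mean() else 0.0
            if p == 1.0:
                logger.info("measure %s: zero variance, identical means", m)
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        out.append(GroupComparison(
            measure=m,
            mean_a=float(xa.mean()),
            mean_b=float(xb.mean()),
            sem_a=float(stats.sem(xa)) if len(xa) > 1 else 0.0,
            sem_b=float(stats.sem(xb)) if len(xb) > 1 else 0.0,
            t_statistic=float(t),
            p_value=float(p),
            bonferroni_alpha=adj,
        ))
    return out
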