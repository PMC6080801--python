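"""Reading, validating and normalising digitised spatial duct networks.

A digitised ductal network is a spatially embedded, undirected, simple
graph: nodes are terminal ends and duct intersections with 3D positions,
edges are the duct segments connecting them, and one designated *root*
node is the exit into the duodenum.  Samples ship as a pair of tables —
one listing node IDs with their positions, one listing connectivity (and
optionally measured duct lengths).  :class:`SpatialNetwork` is the
in-memory form consumed by every other module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SpatialNetwork",
    "ValidationError",
    "read_network",
    "read_network_xlsx",
    "write_network",
    "to_json",
    "from_json",
    "to_adjacency",
    "contract_degree2",
]

#: relative tolerance for checking stored lengths against Euclidean distances
LENGTH_RTOL = 1e-9


class ValidationError(ValueError):
    """Raised when a network violates the structural contract."""


def _canon(u: int, v: int) -> tuple[int, int]:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class SpatialNetwork:
    """A rooted, spatially embedded, simple undirected network.

    Parameters
    ----------
    node_ids
        Integer node labels (arbitrary, need not be contiguous).
    positions
    	``(N, 3)`` array of coordinates, one row per node in ``node_ids``
        order.  Planar samples carry ``z = 0``.
    edges
        Unordered node-ID pairs; stored canonically sorted.
    edge_lengths
        Mapping from canonical edge to positive duct length.  Missing
        entries are filled with the Euclidean endpoint distance
        (digitised ducts are curved, so a stored measured length wins
        over the straight-line recomputation).
    root_id
        The exit node; distances to the root are measured to it.
    name
        Free-text sample label.
    """

    node_ids: list[int]
    positions: np.ndarray
    edges: list[tuple[int, int]]
    edge_lengths: dict[tuple[int, int], float] = field(default_factory=dict)
    root_id: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.node_ids = [int(i) for i in self.node_ids]
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (len(self.node_ids), 3):
            raise ValidationError(
                f"positions must be ({len(self.node_ids)}, 3), "
                f"got {self.positions.shape}"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            dupes = sorted({i for i in self.node_ids if self.node_ids.count(i) > 1})
            raise ValidationError(f"duplicate node IDs: {dupes}")
        if self.root_id is None and self.node_ids:
            self.root_id = min(self.node_ids)
        if self.root_id not in set(self.node_ids):
            raise ValidationError(f"root node {self.root_id} not in node_ids")

        idset = set(self.node_ids)
        seen: set[tuple[int, int]] = set()
        canon_edges: list[tuple[int, int]] = []
        for u, v in self.edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValidationError(f"self-edge at node {u}")
            for w in (u, v):
                if w not in idset:
                    raise ValidationError(
                        f"edge ({u}, {v}) references unknown node {w}"
                    )
            e = _canon(u, v)
            if e in seen:
                continue  # deduplicate order-insensitively
            seen.add(e)
            canon_edges.append(e)
        self.edges = canon_edges

        lengths: dict[tuple[int, int], float] = {}
        for e in self.edges:
            raw = self.edge_lengths.get(e, self.edge_lengths.get((e[1], e[0])))
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raw = self.euclidean_length(*e)
            raw = float(raw)
            if raw <= 0:
                raise ValidationError(f"non-positive length {raw} for edge {e}")
            lengths[e] = raw
        self.edge_lengths = lengths

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_length(self) -> float:
        """Sum of all duct lengths, L_tot."""
        return float(sum(self.edge_lengths.values()))

    def index_of(self, node_id: int) -> int:
        """Dense 0-based index of a node ID (order of ``node_ids``)."""
        return self._id_to_index[node_id]

    @property
    def _id_to_index(self) -> dict[int, int]:
        return {nid: i for i, nid in enumerate(self.node_ids)}

    def position_of(self, node_id: int) -> np.ndarray:
        return self.positions[self.index_of(node_id)]

    def euclidean_length(self, u: int, v: int) -> float:
        idx = self._id_to_index
        return float(np.linalg.norm(self.positions[idx[u]] - self.positions[idx[v]]))

    def degree(self, node_id: int) -> int:
        return sum(1 for e in self.edges if node_id in e)

    # -- conversions -----------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        """Weighted :class:`networkx.Graph`; ``length`` is the edge weight."""
        g = nx.Graph()
        for nid, pos in zip(self.node_ids, self.positions):
            g.add_node(nid, pos=tuple(pos))
        for e in self.edges:
            g.add_edge(*e, length=self.edge_lengths[e])
        return g

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        return nx.is_connected(self.to_networkx())

    def with_edges(
        self,
        edges: list[tuple[int, int]],
        edge_lengths: dict[tuple[int, int], float] | None = None,
    ) -> "SpatialNetwork":
        """Copy of this network with a replaced edge set (same nodes/root)."""
        if edge_lengths is None:
            edge_lengths = {
                _canon(*e): self.edge_lengths[_canon(*e)]
                for e in edges
                if _canon(*e) in self.edge_lengths
            }
        return replace(self, edges=list(edges), edge_lengths=dict(edge_lengths))


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _build_from_frames(
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
    root_id: int | None,
    name: str,
    columns: dict[str, str],
) -> SpatialNetwork:
    cols = {"id": "id", "x": "x", "y": "y", "z": "z",
            "source": "source", "target": "target", "length": "length"}
    cols.update(columns or {})
    for c in ("id", "x", "y"):
        if cols[c] not in nodes.columns:
            raise ValidationError(f"nodes table missing column {cols[c]!r}")
    for c in ("source", "target"):
        if cols[c] not in edges.columns:
            raise ValidationError(f"edges table missing column {cols[c]!r}")
    z = nodes[cols["z"]] if cols["z"] in nodes.columns else 0.0
    node_ids = nodes[cols["id"]].astype(int).tolist()
    positions = np.column_stack([
        nodes[cols["x"]].astype(float),
        nodes[cols["y"]].astype(float),
        np.broadcast_to(np.asarray(z, dtype=float), (len(nodes),)),
    ])
    edge_pairs = list(
        zip(edges[cols["source"]].astype(int), edges[cols["target"]].astype(int))
    )
    lengths: dict[tuple[int, int], float] = {}
    if cols["length"] in edges.columns:
        for (u, v), ln in zip(edge_pairs, edges[cols["length"]].astype(float)):
            if not np.isnan(ln):
                lengths[_canon(int(u), int(v))] = float(ln)
    return SpatialNetwork(
        node_ids=node_ids,
        positions=positions,
        edges=edge_pairs,
        edge_lengths=lengths,
        root_id=root_id,
        name=name,
    )


def read_network(
    nodes_table: str,
    edges_table: str,
    root_id: int | None = None,
    name: str = "",
    columns: dict[str, str] | None = None,
) -> SpatialNetwork:
    """Read a sample from a nodes CSV (``id,x,y,z``) and edges CSV
    (``source,target[,length]``).

    Missing ``length`` values are filled with Euclidean endpoint
    distances; duplicate edges are collapsed order-insensitively.
    ``root_id`` defaults to the smallest node ID.
    """
    nodes = pd.read_csv(nodes_table)
    edges = pd.read_csv(edges_table)
    return _build_from_frames(nodes, edges, root_id, name or str(nodes_table),
                              columns or {})


def read_network_xlsx(
    nodes_table: str,
    edges_table: str,
    root_id: int | None = None,
    name: str = "",
    columns: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> SpatialNetwork:
    """Spreadsheet variant of :func:`read_network`.

    Digitised samples are distributed as spreadsheet pairs; the column
    layout is not standardised, so ``columns`` maps the canonical names
    (``id, x, y, z, source, target, length``) onto the sheet's headers.
    """
    nodes = pd.read_excel(nodes_table, sheet_name=sheet)
    edges = pd.read_excel(edges_table, sheet_name=sheet)
    return _build_from_frames(nodes, edges, root_id, name or str(nodes_table),
                              columns or {})


def write_network(net: SpatialNetwork, nodes_table: str, edges_table: str) -> None:
    """Write the CSV pair read back by :func:`read_network`."""
    pd.DataFrame({
        "id": net.node_ids,
        "x": net.positions[:, 0],
        "y": net.positions[:, 1],
        "z": net.positions[:, 2],
    }).to_csv(nodes_table, index=False)
    pd.DataFrame({
        "source": [u for u, _ in net.edges],
        "target": [v for _, v in net.edges],
        "length": [net.edge_lengths[e] for e in net.edges],
    }).to_csv(edges_table, index=False)


def to_json(net: SpatialNetwork, path: str | None = None) -> str:
    """Canonical JSON serialisation (stable field order, full precision)."""
    doc = {
        "name": net.name,
        "root_id": net.root_id,
        "node_ids": net.node_ids,
        "positions": net.positions.tolist(),
        "edges": [list(e) for e in net.edges],
        "edge_lengths": [net.edge_lengths[e] for e in net.edges],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_json(source: str) -> SpatialNetwork:
    """Inverse of :func:`to_json`; accepts a path or a JSON string."""
    if source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    edges = [tuple(e) for e in doc["edges"]]
    return SpatialNetwork(
        node_ids=doc["node_ids"],
        positions=np.asarray(doc["positions"], dtype=float),
        edges=edges,
        edge_lengths={_canon(*e): ln for e, ln in zip(edges, doc["edge_lengths"])},
        root_id=doc["root_id"],
        name=doc.get("name", ""),
    )


# ---------------------------------------------------------------------------
# Adjacency representations
# ---------------------------------------------------------------------------

def to_adjacency(net: SpatialNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Binary adjacency ``A`` and length-weighted adjacency ``A_w``.

    Rows/columns follow the ``node_ids`` order.  ``A`` is symmetric 0/1
    with zero diagonal; ``A_w[i, j] = A[i, j] * d(i, j)`` with ``d`` the
    stored duct length, so ``L_tot = A_w.sum() / 2``.
    """
    n = net.n_nodes
    a = np.zeros((n, n))
    aw = np.zeros((n, n))
    idx = net._id_to_index
    for (u, v), ln in net.edge_lengths.items():
        i, j = idx[u], idx[v]
        a[i, j] = a[j, i] = 1.0
        aw[i, j] = aw[j, i] = ln
    return a, aw


def contract_degree2(net: SpatialNetwork) -> SpatialNetwork:
    """Remove non-root degree-2 nodes, merging their incident ducts.

    Digitisation only marks terminal ends and intersections, so a
    degree-2 node is merely a continuation of a duct.  Each maximal
    chain of degree-2 nodes running between two *distinct* anchor nodes
    (anchors are the root and every node of degree != 2) is replaced by
    a single edge whose length is the sum of the chain's edge lengths.
    Total length and cycle-space dimension (E - N + 1) are preserved.

    Degenerate cases: a closed loop of degree-2 nodes hanging off a
    single anchor cannot be contracted without a self-loop and raises
    :class:`ValidationError`; a component that is itself a bare cycle
    (every node degree 2, e.g. a triangle) has no junctions to merge
    into and is returned unchanged.  Two parallel chains between the
    same anchor pair would collide into a multi-edge, so the second
    chain retains one interior node to keep the graph simple (and the
    cycle space intact).
    """
    g = net.to_networkx()
    root = net.root_id

    def is_anchor(n: int) -> bool:
        return n == root or g.degree(n) != 2

    anchors = [n for n in g.nodes if is_anchor(n)]
    if len(anchors) <= 1 and all(g.degree(n) == 2 for n in g.nodes):
        return net  # bare cycle: nothing but continuations, leave intact

    out = nx.Graph()
    out.add_nodes_from(anchors)
    visited_edges: set[tuple[int, int]] = set()
    kept_interior: set[int] = set()

    def add_contracted(u: int, v: int, length: float, chain: list[int]) -> None:
        if u == v:
            raise ValidationError(
                f"cycle of degree-2 nodes through {chain} closes on node {u}; "
                "contraction would create a self-loop"
            )
        if out.has_edge(u, v):
            # parallel chain between the same anchors; chains are added
            # shortest-first, so this one always has interior nodes
            interior = chain[1:-1]
            mid = interior[len(interior) // 2]
            kept_interior.add(mid)
            out.add_node(mid)
            left = right = 0.0
            side = chain[: chain.index(mid) + 1]
            for a, b in zip(side, side[1:]):
                left += g[a][b]["length"]
            right = length - left
            out.add_edge(u, mid, length=left)
            out.add_edge(mid, v, length=right)
            return
        out.add_edge(u, v, length=length)

    chains: list[tuple[int, int, float, list[int]]] = []
    for a in anchors:
        for nbr in g.neighbors(a):
            if (_canon(a, nbr)) in visited_edges:
                continue
            chain = [a, nbr]
            visited_edges.add(_canon(a, nbr))
            length = g[a][nbr]["length"]
            prev, cur = a, nbr
            while not is_anchor(cur):
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                visited_edges.add(_canon(cur, nxt))
                length += g[cur][nxt]["length"]
                chain.append(nxt)
                prev, cur = cur, nxt
            chains.append((a, cur, length, chain))
    for a, b, length, chain in sorted(chains, key=lambda c: len(c[3])):
        add_contracted(a, b, length, chain)

    kept = [n for n in net.node_ids if n in out]
    idx = net._id_to_index
    return SpatialNetwork(
        node_ids=kept,
        positions=net.positions[[idx[n] for n in kept]],
        edges=[_canon(u, v) for u, v in out.edges],
        edge_lengths={_canon(u, v): d["length"] for u, v, d in out.edges(data=True)},
        root_id=root,
        name=net.name,
    )
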