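"""Synthetic inputs: exact fixtures, plexus-like meshes, and tree stand-ins.

The digitised embryonic samples are not publicly downloadable, so every
stage of the pipeline is exercised on generated data instead:

* named small fixtures with hand-checkable statistics (triangle,
  cycles, K4, paths, stars, binary trees);
* jittered triangular-lattice meshes — planar, loop-rich, rooted at a
  boundary node — as a growth-model-independent control for the metric
  suite;
* plexus stand-ins from the growth model at its best-fit parameters
  (lambda = 0.25, Delta = 1, ~320 nodes), emulating the
  early (E12.5-like) network;
* tree stand-ins (single-link growth, lambda = Delta = 0) emulating the
  pruned late (E18.5-like) network.

All generators are deterministic given (generator, parameters, seed),
and every output is connected, simple and rooted.  ``emit_sample_set``
writes the two-table-per-sample file layout that ``io_core`` reads
back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .io_core import SpatialNetwork, _canon, write_network
from .growth_model import GrowthParams, grow_network

__all__ = [
    "SynthConfig",
    "make_fixtures",
    "make_lattice_mesh",
    "make_plexus",
    "make_tree",
    "generate",
    "emit_sample_set",
]


@dataclass
class SynthConfig:
    """Recipe for one synthetic sample."""

    generator: str = "plexus"
    n_nodes: int = 320
    noise: float = 0.0
    dilution: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.generator not in ("fixture", "lattice_mesh", "plexus", "tree"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if not 0.0 <= self.dilution <= 1.0:
            raise ValueError("dilution must be in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


# ---------------------------------------------------------------------------
# Exact fixtures
# ---------------------------------------------------------------------------

def _net(ids, pos, edges, root=None, name="") -> SpatialNetwork:
    return SpatialNetwork(
        node_ids=list(ids),
        positions=np.asarray(pos, dtype=float),
        edges=list(edges),
        root_id=root,
        name=name,
    )


def _cycle(n: int, name: str) -> SpatialNetwork:
    ang = 2 * np.pi * np.arange(n) / n
    pos = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
    edges = [(i + 1, (i + 1) % n + 1) for i in range(n)]
    return _net(range(1, n + 1), pos, edges, root=1, name=name)


def _binary_tree(depth: int) -> SpatialNetwork:
    """Balanced binary tree of 2^(depth+1) - 1 nodes, rooted at the top;
    level k sits at height -k with horizontal fan-out."""
    n = 2 ** (depth + 1) - 1
    ids = list(range(1, n + 1))
    pos = []
    for i in ids:
        level = int(np.floor(np.log2(i)))
        rank = i - 2**level
        width = 2**level
        x = (rank + 0.5) / width - 0.5
        pos.append([4.0 * x, -float(level), 0.0])
    edges = [(i // 2, i) for i in ids if i > 1]
    return _net(ids, pos, edges, root=1, name=f"binary_tree_{depth}")


def make_fixtures() -> dict[str, SpatialNetwork]:
    """Named exact fixtures with documented coordinates."""
    fixtures: dict[str, SpatialNetwork] = {}
    fixtures["triangle"] = _cycle(3, "triangle")
    fixtures["cycle4"] = _cycle(4, "cycle4")
    fixtures["cycle5"] = _cycle(5, "cycle5")

    k4_pos = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0], [0.5, 0.3, 0.8]]
    fixtures["k4"] = _net(
        range(1, 5), k4_pos,
        [(i, j) for i in range(1, 5) for j in range(i + 1, 5)],
        root=1, name="k4",
    )

    n = 10
    fixtures["path10"] = _net(
        range(1, n + 1),
        [[float(i), 0, 0] for i in range(n)],
        [(i, i + 1) for i in range(1, n)],
        root=1, name="path10",
    )

    ang = 2 * np.pi * np.arange(5) / 5
    star_pos = [[0, 0, 0]] + [[np.cos(a), np.sin(a), 0] for a in ang]
    fixtures["star6"] = _net(
        range(1, 7), star_pos, [(1, i) for i in range(2, 7)],
        root=1, name="star6",
    )

    sq = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
    fixtures["square_perimeter"] = _net(
        range(1, 5), sq, [(1, 2), (2, 3), (3, 4), (4, 1)],
        root=1, name="square_perimeter",
    )

    # unit square with midside points and two pendant terminals at
    # opposite corners, so corners are genuine junctions/terminals and
    # each side is a contractible 2-edge chain
    sub_pos = sq + [[0.5, 0, 0], [1, 0.5, 0], [0.5, 1, 0], [0, 0.5, 0],
                    [-0.5, -0.5, 0], [1.5, 1.5, 0]]
    fixtures["subdivided_square"] = _net(
        range(1, 11), sub_pos,
        [(1, 5), (5, 2), (2, 6), (6, 3), (3, 7), (7, 4), (4, 8), (8, 1),
         (1, 9), (3, 10)],
        root=1, name="subdivided_square",
    )

    for depth in (2, 3, 4):
        fixtures[f"binary_tree_{depth}"] = _binary_tree(depth)
    return fixtures


# ---------------------------------------------------------------------------
# Lattice mesh
# ---------------------------------------------------------------------------

def make_lattice_mesh(config: SynthConfig) -> SpatialNetwork:
    """Jittered triangular-lattice patch, optionally diluted.

    A planar triangular lattice of about ``n_nodes`` nodes; positions
    jittered by ``noise`` (lattice units, isotropic Gaussian in-plane),
    then a ``dilution`` fraction of the redundant (non-bridge) edges
    removed uniformly at random so the graph stays connected.  The root
    is the boundary node nearest the origin.  Loop-rich, dimension ~2.
    """
    if config.n_nodes < 16:
        raise ValueError("lattice mesh needs n_nodes >= 16")
    rng = np.random.default_rng(config.seed)
    # an (m, n) triangular lattice has (m + 1) * (n // 2 + 1) nodes
    m = max(3, int(round(np.sqrt(config.n_nodes))) - 1)
    cols = max(1, int(np.ceil(config.n_nodes / (m + 1))) - 1)
    g = nx.triangular_lattice_graph(m, 2 * cols)
    g = nx.convert_node_labels_to_integers(
        nx.Graph(g), first_label=1, label_attribute="old"
    )
    ids = sorted(g.nodes)
    pos = {n: g.nodes[n]["pos"] for n in ids}
    positions = np.array([[pos[n][0], pos[n][1], 0.0] for n in ids])
    if config.noise > 0:
        positions[:, :2] += rng.normal(scale=config.noise,
                                       size=(len(ids), 2))
    net = SpatialNetwork(
        node_ids=ids,
        positions=positions,
        edges=[_canon(u, v) for u, v in g.edges],
        root_id=1,
        name=config.name or f"lattice_{config.seed}",
    )
    if config.dilution > 0:
        from .flux_pruning import redundant_edges

        n_remove = int(round(config.dilution
                             * (net.n_edges - (net.n_nodes - 1))))
        for _ in range(n_remove):
            red = sorted(redundant_edges(net))
            if not red:
                break
            edge = red[int(rng.integers(0, len(red)))]
            net = net.with_edges([e for e in net.edges if e != edge])
    return net


# ---------------------------------------------------------------------------
# Growth-model stand-ins
# ---------------------------------------------------------------------------

def make_plexus(config: SynthConfig) -> SpatialNetwork:
    """Early-plexus stand-in: growth model at the best-fit plexus
    parameters (lambda = 0.25, Delta = 1), default 320 nodes."""
    return grow_network(GrowthParams(
        lambda_mean=0.25,
        delta_pool=1,
        n_target=config.n_nodes,
        seed=config.seed,
    ))


def make_tree(config: SynthConfig) -> SpatialNetwork:
    """Late-stage tree stand-in: single-link growth (lambda = Delta = 0)
    yields a spatially embedded random tree with zero polygons."""
    return grow_network(GrowthParams(
        lambda_mean=0.0,
        delta_pool=0,
        n_target=config.n_nodes,
        seed=config.seed,
    ))


def generate(config: SynthConfig) -> SpatialNetwork:
    """Dispatch a :class:`SynthConfig` to its generator."""
    if config.generator == "fixture":
        fixtures = make_fixtures()
        if config.name not in fixtures:
            raise ValueError(
                f"unknown fixture {config.name!r}; "
                f"choose from {sorted(fixtures)}"
            )
        return fixtures[config.name]
    if config.generator == "lattice_mesh":
        return make_lattice_mesh(config)
    if config.generator == "plexus":
        return make_plexus(config)
    return make_tree(config)


def emit_sample_set(
    out_dir: str | Path,
    configs: list[SynthConfig],
) -> dict:
    """Write one nodes/edges CSV pair per config plus a JSON manifest.

    The manifest records each sample's config (including seed), so the
    exact same files can be regenerated; ``io_core.read_network``
    round-trips every emitted pair.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"samples": []}
    for i, cfg in enumerate(configs):
        net = generate(cfg)
        stem = cfg.name or f"{cfg.generator}_{cfg.seed}_{i}"
        nodes_path = out / f"{stem}_nodes.csv"
        edges_path = out / f"{stem}_edges.csv"
        write_network(net, str(nodes_path), str(edges_path))
        manifest["samples"].append({
            "name": stem,
            "nodes": nodes_path.name,
            "edges": edges_path.name,
            "root_id": net.root_id,
            "config": asdict(cfg),
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
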