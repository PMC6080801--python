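"""Steady-state diffusion on the duct network and flux-driven pruning.

Fluid secreted at the terminal ends (or, in a variant, at every node)
drains through the network to the root/exit.  The concentration field
phi on the nodes obeys discrete diffusion with the combinatorial graph
Laplacian ``L = D - A``:

    d phi / dt = -C L phi,

with Dirichlet boundaries ``phi = 1`` at terminals (degree-1 non-root
nodes) and ``phi = 0`` at the root.  At steady state the per-edge flux
is ``Q(i, j) = C (phi_i - phi_j)``; interior nodes conserve flux.  The
Laplacian is deliberately unweighted — duct lengths do not modulate
conductance — so only the topology and the boundary placement shape the
flux field.

Pruning removes, one at a time, the redundant (non-bridge) link with
the lowest flux magnitude, re-solving the diffusion after every removal
until the network is a spanning tree.  A random-pruning baseline
removes uniformly random redundant links instead.  The trace of removal
events (flux and distance to root per event) shows that flux-based
pruning proceeds from the periphery toward the outlet.

The steady state is computed by directly solving the boundary-clamped
linear system (production path); the forward-Euler iteration of the
same scheme is retained as an independent cross-check and matches the
direct solve to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .io_core import SpatialNetwork, _canon, to_adjacency
from .metrics import _weighted_sparse

__all__ = [
    "DiffusionConfig",
    "FluxState",
    "PruneTrace",
    "PruneEvent",
    "laplacian",
    "solve_steady_state",
    "redundant_edges",
    "prune_by_flux",
    "prune_random",
]


@dataclass
class DiffusionConfig:
    """Numerical configuration for the diffusion solve.

    ``dt = None`` picks ``1 / (2 * max_degree + 1)``, inside the Euler
    stability bound ``C * dt < 1 / (2 * max_degree)``; ``tol = None``
    picks ``1e-10 * N``.  ``source_mode`` is ``"terminals_only"``
    (clamp terminals at 1, root at 0) or ``"all_nodes"`` (unit inflow at
    every non-root node, root clamped at 0 — the ductal-secretion
    variant; only relative fluxes matter, the scale is arbitrary).
    """

    diffusion_coeff: float = 1.0
    dt: float | None = None
    tol: float | None = None
    max_steps: int = 10_000_000
    source_mode: str = "terminals_only"

    def __post_init__(self) -> None:
        if self.diffusion_coeff <= 0:
            raise ValueError("diffusion_coeff must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.source_mode not in ("terminals_only", "all_nodes"):
            raise ValueError(f"unknown source_mode {self.source_mode!r}")


@dataclass
class FluxState:
    """Steady-state concentrations and per-edge fluxes.

    ``flux`` maps each canonical edge ``(u, v), u < v`` to the signed
    flux from u to v; use :meth:`magnitude` for the non-negative size.
    """

    phi: dict[int, float]
    flux: dict[tuple[int, int], float]

    def magnitude(self, u: int, v: int) -> float:
        return abs(self.flux[_canon(u, v)])

    def net_flux(self, node: int) -> float:
        """Signed net outflow at a node (≈ 0 at interior nodes)."""
        total = 0.0
        for (a, b), q in self.flux.items():
            if a == node:
                total += q
            elif b == node:
                total -= q
        return total


@dataclass
class PruneEvent:
    """One pruning event: the removed edge, its flux at removal (None
    for random pruning) and its distance to the root measured on the
    network just before the removal."""

    index: int
    edge: tuple[int, int]
    flux: float | None
    dist_to_root: float


@dataclass
class PruneTrace:
    events: list[PruneEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def distances(self) -> np.ndarray:
        return np.array([e.dist_to_root for e in self.events])

    @property
    def fluxes(self) -> np.ndarray:
        return np.array([e.flux for e in self.events], dtype=float)


# ---------------------------------------------------------------------------
# Laplacian & steady state
# ---------------------------------------------------------------------------

def laplacian(net: SpatialNetwork) -> np.ndarray:
    """Combinatorial (unweighted) graph Laplacian ``L = D - A``."""
    a, _ = to_adjacency(net)
    return np.diag(a.sum(axis=1)) - a


def terminal_nodes(net: SpatialNetwork) -> list[int]:
    """Degree-1 nodes other than the root (the secreting acinar ends)."""
    deg = dict.fromkeys(net.node_ids, 0)
    for u, v in net.edges:
        deg[u] += 1
        deg[v] += 1
    return [n for n in net.node_ids if deg[n] == 1 and n != net.root_id]


def _boundary_and_source(
    net: SpatialNetwork, config: DiffusionConfig
) -> tuple[dict[int, float], np.ndarray]:
    """(clamped node -> value, per-node source vector)."""
    n = net.n_nodes
    source = np.zeros(n)
    clamped = {net.root_id: 0.0}
    if config.source_mode == "terminals_only":
        terms = terminal_nodes(net)
        if not terms:
            raise ValueError(
                "terminals_only source needs at least one degree-1 "
                "non-root node"
            )
        for t in terms:
            clamped[t] = 1.0
    else:
        ri = net.index_of(net.root_id)
        source[:] = 1.0
        source[ri] = 0.0
    return clamped, source


def _steady_direct(
    net: SpatialNetwork, config: DiffusionConfig
) -> np.ndarray:
    lap = laplacian(net)
    n = net.n_nodes
    clamped, source = _boundary_and_source(net, config)
    idx = net._id_to_index
    phi = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    for node, val in clamped.items():
        fixed[idx[node]] = True
        phi[idx[node]] = val
    free = ~fixed
    c = config.diffusion_coeff
    # steady state of d(phi)/dt = -C L phi + source on free nodes:
    # C * L_ff phi_f = source_f - C * L_fc phi_c
    lff = lap[np.ix_(free, free)]
    rhs = source[free] - c * lap[np.ix_(free, fixed)] @ phi[fixed]
    phi[free] = np.linalg.solve(c * lff, rhs)
    return phi


def _steady_euler(
    net: SpatialNetwork, config: DiffusionConfig
) -> np.ndarray:
    lap = laplacian(net)
    n = net.n_nodes
    clamped, source = _boundary_and_source(net, config)
    idx = net._id_to_index
    c = config.diffusion_coeff
    max_deg = int(lap.diagonal().max()) if n else 0
    dt = config.dt if config.dt is not None else 1.0 / (c * (2 * max_deg + 1))
    if c * dt >= 1.0 / (2 * max_deg):
        raise ValueError(
            f"unstable step: C*dt = {c * dt:.3g} >= 1/(2*max_degree) = "
            f"{1.0 / (2 * max_deg):.3g}"
        )
    tol = config.tol if config.tol is not None else 1e-10 * n
    phi = np.zeros(n)
    cvals = {idx[k]: v for k, v in clamped.items()}
    for i, v in cvals.items():
        phi[i] = v
    for _ in range(config.max_steps):
        new = phi - c * dt * (lap @ phi) + dt * source
        for i, v in cvals.items():
            new[i] = v
        change = float(np.abs(new - phi).sum())
        phi = new
        if change < tol:
            return phi
    raise RuntimeError(
        f"no steady state within {config.max_steps} steps "
        f"(residual change {change:.3g} > tol {tol:.3g})"
    )


def solve_steady_state(
    net: SpatialNetwork,
    config: DiffusionConfig | None = None,
    method: str = "direct",
) -> FluxState:
    """Steady-state concentration field and per-edge fluxes.

    ``method="direct"`` solves the clamped linear system exactly;
    ``method="euler"`` runs the forward-Euler iteration with boundary
    re-clamping after each step until the total concentration change
    per step drops below tolerance.  Both give the same steady state.
    """
    config = config or DiffusionConfig()
    if not net.is_connected():
        raise ValueError("diffusion requires a connected network")
    if method == "direct":
        phi = _steady_direct(net, config)
    elif method == "euler":
        phi = _steady_euler(net, config)
    else:
        raise ValueError(f"unknown method {method!r}")
    idx = net._id_to_index
    c = config.diffusion_coeff
    flux = {
        e: c * (phi[idx[e[0]]] - phi[idx[e[1]]])
        for e in net.edges
    }
    return FluxState(
        phi={nid: float(phi[i]) for i, nid in enumerate(net.node_ids)},
        flux=flux,
    )


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def redundant_edges(net: SpatialNetwork) -> set[tuple[int, int]]:
    """Edges whose removal does not fragment the network (non-bridges)."""
    g = net.to_networkx()
    bridges = {_canon(u, v) for u, v in nx.bridges(g)}
    return {e for e in net.edges if e not in bridges}


def _dist_to_root(net: SpatialNetwork, edge: tuple[int, int]) -> float:
    """Weighted shortest-path distance from the edge's closer endpoint
    to the root, on the given network."""
    d = dijkstra(
        _weighted_sparse(net), directed=False,
        indices=net.index_of(net.root_id),
    )
    return float(min(d[net.index_of(edge[0])], d[net.index_of(edge[1])]))


def prune_by_flux(
    net: SpatialNetwork,
    config: DiffusionConfig | None = None,
) -> tuple[SpatialNetwork, PruneTrace]:
    """Remove the lowest-flux redundant link, re-solve the diffusion,
    and repeat until the network is a spanning tree.

    One link is removed per diffusion re-solve; ties in flux are broken
    lexicographically on the sorted node-ID pair.  Each trace event
    records the removed edge's flux and its distance to the root on the
    pre-removal network.
    """
    config = config or DiffusionConfig()
    trace = PruneTrace()
    current = net
    index = 0
    while True:
        red = redundant_edges(current)
        if not red:
            break
        state = solve_steady_state(current, config)
        edge = min(red, key=lambda e: (abs(state.flux[e]), e))
        trace.events.append(PruneEvent(
            index=index,
            edge=edge,
            flux=abs(state.flux[edge]),
            dist_to_root=_dist_to_root(current, edge),
        ))
        current = current.with_edges([e for e in current.edges if e != edge])
        index += 1
    return current, trace


def prune_random(
    net: SpatialNetwork,
    seed: int = 0,
) -> tuple[SpatialNetwork, PruneTrace]:
    """Baseline: remove uniformly random redundant links until a tree
    remains; the trace carries distances but no flux values."""
    rng = np.random.default_rng(seed)
    trace = PruneTrace()
    current = net
    index = 0
    while True:
        red = sorted(redundant_edges(current))
        if not red:
            break
        edge = red[int(rng.integers(0, len(red)))]
        trace.events.append(PruneEvent(
            index=index,
            edge=edge,
            flux=None,
            dist_to_root=_dist_to_root(current, edge),
        ))
        current = current.with_edges([e for e in current.edges if e != edge])
        index += 1
    return current, trace
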