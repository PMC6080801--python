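"""Flux-diameter adaptation on pruned duct trees.

Each duct adapts its diameter to the shear stress of the fluid it
carries:

    dd/dt = K [tau(t) - tau_desired] d(t),

with the wall shear stress from Poiseuille flow of a laminar,
incompressible fluid,

    tau = 32 eta Q / (pi d^3).

At steady state every duct has tau = tau_desired, hence

    d = (32 eta Q / (pi tau_desired))^(1/3)  —  d proportional to Q^(1/3).

On a rooted tree with uniform secretion, the flux through a duct is
proportional to its drained basin — the number of nodes (or total duct
length) upstream of it — so basin size should scale as the cube of duct
diameter.  This module computes drained basins, the closed-form steady
diameter, the explicit-Euler integration of the adaptation ODE (which
converges to the closed form from any positive start, and lets two
parallel ducts sharing a fixed flow compete until one vanishes), and
the log-log power-law fit used to read off the exponent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .io_core import SpatialNetwork, _canon

__all__ = [
    "AdaptationParams",
    "DuctGeometry",
    "drained_basin",
    "steady_diameter",
    "simulate_adaptation_ode",
    "simulate_competing_pair",
    "fit_powerlaw",
]


@dataclass
class AdaptationParams:
    """K (adaptation rate), tau_desired (target shear stress), eta
    (fluid viscosity), and the ODE step/tolerance.  Units are arbitrary
    but consistent; defaults put the steady diameter at order 1 for
    order-1 fluxes."""

    adaptation_constant: float = 0.1
    tau_desired: float = 1.0
    viscosity: float = 1.0
    dt_ode: float = 1e-3
    tol_ode: float = 1e-10
    max_steps: int = 10_000_000

    def __post_init__(self) -> None:
        for name in ("adaptation_constant", "tau_desired", "viscosity",
                     "dt_ode", "tol_ode"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DuctGeometry:
    """Per-edge geometry of a rooted duct tree.

    ``basin_nodes[e]`` / ``basin_length[e]`` count the nodes / total
    duct length strictly upstream of edge ``e`` (the subtree on the far
    side from the root, including the edge's own upstream endpoint but
    not the edge itself); ``flux`` and ``diameter`` are filled by the
    adaptation step.
    """

    edges: list[tuple[int, int]]
    basin_nodes: dict[tuple[int, int], int]
    basin_length: dict[tuple[int, int], float]
    flux: dict[tuple[int, int], float] | None = None
    diameter: dict[tuple[int, int], float] | None = None


def drained_basin(tree: SpatialNetwork) -> DuctGeometry:
    """Drained basin of every duct of a rooted tree.

    For each edge, counts the nodes and sums the duct lengths in the
    subtree hanging below it (away from the root).  A leaf edge drains
    exactly 1 node; the basins of the edges incident to the root
    partition the other N - 1 nodes.
    """
    g = tree.to_networkx()
    if g.number_of_edges() != g.number_of_nodes() - 1 or not nx.is_connected(g):
        raise ValueError(
            "drained_basin requires a tree; prune the network first"
        )
    root = tree.root_id
    order = list(nx.dfs_postorder_nodes(g, source=root))
    parent = {root: None}
    for u, v in nx.dfs_edges(g, source=root):
        parent[v] = u
    sub_nodes = dict.fromkeys(g.nodes, 1)
    sub_len = dict.fromkeys(g.nodes, 0.0)
    basin_nodes: dict[tuple[int, int], int] = {}
    basin_length: dict[tuple[int, int], float] = {}
    for v in order:
        p = parent[v]
        if p is None:
            continue
        e = _canon(p, v)
        basin_nodes[e] = sub_nodes[v]
        basin_length[e] = sub_len[v]
        sub_nodes[p] += sub_nodes[v]
        sub_len[p] += sub_len[v] + g[p][v]["length"]
    return DuctGeometry(
        edges=list(basin_nodes),
        basin_nodes=basin_nodes,
        basin_length=basin_length,
    )


def _tau(d: np.ndarray, q: np.ndarray, eta: float) -> np.ndarray:
    return 32.0 * eta * q / (np.pi * d**3)


def steady_diameter(
    q: np.ndarray | list[float],
    params: AdaptationParams | None = None,
) -> np.ndarray:
    """Closed-form steady diameter ``(32 eta Q / (pi tau_desired))^(1/3)``.

    Zero flux gives zero diameter (the duct vanishes); negative flux is
    an error — pass magnitudes.
    """
    params = params or AdaptationParams()
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("flux must be >= 0")
    return (32.0 * params.viscosity * q / (np.pi * params.tau_desired)) ** (1.0 / 3.0)


def simulate_adaptation_ode(
    q: np.ndarray | list[float],
    params: AdaptationParams | None = None,
    d0: np.ndarray | list[float] | None = None,
    record_every: int = 0,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Integrate dd/dt = K (tau - tau_desired) d per duct (fixed fluxes).

    Explicit Euler until the largest relative change per step falls
    below ``tol_ode``; converges to :func:`steady_diameter` from any
    positive start.  With ``record_every > 0`` also returns the sampled
    trajectory (steps x ducts).  Raises if a step drives a diameter to
    zero or below (step size too large for the given K).
    """
    params = params or AdaptationParams()
    q = np.asarray(q, dtype=float)
    if (q <= 0).any():
        raise ValueError("ODE integration needs strictly positive fluxes")
    if d0 is None:
        d = np.ones_like(q)
    else:
        d = np.asarray(d0, dtype=float).copy()
    if (d <= 0).any():
        raise ValueError("initial diameters must be > 0")
    snapshots = [d.copy()] if record_every else None
    k, dt = params.adaptation_constant, params.dt_ode
    for step in range(1, params.max_steps + 1):
        tau = _tau(d, q, params.viscosity)
        new = d + dt * k * (tau - params.tau_desired) * d
        if (new <= 0).any():
            raise RuntimeError(
                "adaptation step drove a diameter <= 0; reduce dt_ode"
            )
        rel = float(np.max(np.abs(new - d) / d))
        d = new
        if record_every and step % record_every == 0:
            snapshots.append(d.copy())
        if rel < params.tol_ode:
            break
    else:
        raise RuntimeError(
            f"no ODE steady state within {params.max_steps} steps"
        )
    if record_every:
        return d, np.vstack(snapshots)
    return d


def simulate_competing_pair(
    q_total: float,
    params: AdaptationParams | None = None,
    d0: tuple[float, float] = (1.0, 1.1),
    max_steps: int | None = None,
) -> tuple[float, float]:
    """Two parallel ducts sharing a fixed total flow.

    The flow splits by Poiseuille conductance (proportional to d^4 at
    equal length and pressure drop).  Any asymmetry is amplified: the
    narrower duct loses flow, shrinks further and vanishes, while the
    wider one converges to the steady diameter for the whole flow.
    Returns the final diameter pair (the loser clipped at ~0).
    """
    params = params or AdaptationParams()
    d = np.asarray(d0, dtype=float)
    if (d <= 0).any():
        raise ValueError("initial diameters must be > 0")
    k, dt = params.adaptation_constant, params.dt_ode
    steps = max_steps or params.max_steps
    floor = 1e-9
    for _ in range(steps):
        g = d**4
        q = q_total * g / g.sum()
        tau = _tau(np.maximum(d, floor), q, params.viscosity)
        new = d + dt * k * (tau - params.tau_desired) * d
        new = np.maximum(new, floor)
        if np.max(np.abs(new - d) / np.maximum(d, floor)) < params.tol_ode:
            d = new
            break
        d = new
    return float(d[0]), float(d[1])


def fit_powerlaw(
    basin: np.ndarray | list[float],
    diameter: np.ndarray | list[float],
) -> tuple[float, float, float]:
    """Least-squares line on log(diameter) -> log(basin).

    Returns ``(exponent, intercept, r_squared)`` with
    ``basin ≈ exp(intercept) * diameter^exponent`` — an exponent of 3
    is the Poiseuille expectation.  Non-positive pairs are dropped (the
    count is logged); fewer than 3 survivors is an error.
    """
    basin = np.asarray(basin, dtype=float)
    diameter = np.asarray(diameter, dtype=float)
    keep = (basin > 0) & (diameter > 0)
    dropped = int((~keep).sum())
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "fit_powerlaw: dropped %d non-positive pairs", dropped
        )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 positive (basin, diameter) pairs")
    x = np.log(diameter[keep])
    y = np.log(basin[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2
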