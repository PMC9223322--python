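"""Micro-reentrant substrate detection via a discrete diffusion model.

A location can harbour micro-anatomical reentry when unidirectional
conduction block at a node leaves a closed alternative pathway at least
one refractory wavelength long: the wavefront blocked across one edge
travels around the loop and re-enters the blocked fibre from behind once
the tissue has recovered.  With the refractory wavelength expressed as an
integer number of node steps, tau, the criterion is

    reentry at (node, blocked direction)  <=>  tau <= L < infinity,

where L is the *shortest return length*: one step for the blocked edge
plus the shortest path between its endpoints avoiding that edge.

Two routes compute this:

* :func:`simulate_block` runs the discrete diffusion model (DDM) —
  synchronous excitation, one-step excited state, tau-step refractoriness,
  transient unidirectional block on first arrival — and reads reentry off
  the activation times.  By default the paced wavefront is delivered at
  the blocked fibre itself, i.e. the dynamics are observed from the moment
  the wave hits the block, which makes the outcome independent of where
  the beat originated and equal to the graph criterion by construction.
* :func:`shortest_return_length` / :func:`find_substrate` evaluate the
  graph criterion directly; the full-network scan runs on compiled BFS
  kernels, once per undirected edge (the return length is symmetric in
  the blocked direction).

The DDM deliberately contains no electrophysiology — no conduction
velocities, action potentials or source-sink effects.  It isolates the
structural question only: does the network contain the loop?
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .network import SpatialNetwork

logger = logging.getLogger(__name__)


@dataclass
class DDMConfig:
    """Parameters of the discrete diffusion model.

    tau
        Refractory wavelength in node steps (node spacing is one voxel, so
        tau ~ wavelength / voxel edge).  Must be >= 2.
    max_steps
        Simulation/search horizon; loops longer than this are not
        detected.  ``None`` means the network size (no effective bound).
    pacing
        ``"block"`` (default) delivers the paced wavefront at the blocked
        fibre; alternatively an explicit sequence of source node ids.
    block_rule
        Only ``"uniform"`` is implemented: every (node, incoming-direction)
        pair is equally susceptible to block.
    """

    tau: int = 20
    max_steps: int | None = None
    pacing: object = "block"
    block_rule: str = "uniform"

    def __post_init__(self) -> None:
        if self.tau < 2:
            raise ValueError("tau must be >= 2")
        if self.max_steps is not None and self.max_steps <= self.tau:
            raise ValueError("max_steps must exceed tau")
        if self.block_rule != "uniform":
            raise ValueError("only the uniform block rule is implemented")

    def horizon(self, n_nodes: int) -> int:
        return self.max_steps if self.max_steps is not None else max(n_nodes, self.tau + 1)


@dataclass
class Circuit:
    """One reentrant loop: a closed walk through the blocked edge."""

    nodes: np.ndarray  # loop sequence b, ..., n (closing edge n->b implicit)
    length: int  # number of edges in the loop
    blocked: tuple[int, int]  # (node, blocked_neighbour)

    def voxel_set(self, voxels: np.ndarray) -> np.ndarray:
        """Unique home voxels visited by the loop, shape (k, 3)."""
        return np.unique(voxels[self.nodes], axis=0)


@dataclass
class SubstrateResult:
    substrate_nodes: np.ndarray  # nodes with >= 1 reentry-inducing block
    pairs: np.ndarray  # (N, 2) inducing (node, blocked_neighbour) pairs
    circuits: list[Circuit]
    per_voxel_counts: np.ndarray  # 3-d grid of circuit membership counts
    n_substrates: int  # N: number of inducing (node, direction) pairs
    n_opportunities: int  # total (node, direction) pairs evaluated
    tau: int
    provenance: dict = dc_field(default_factory=dict)


def shortest_return_length(
    net: SpatialNetwork, node: int, blocked_neighbour: int
) -> float:
    """Shortest loop length through edge (blocked_neighbour, node).

    One plus the shortest path from ``blocked_neighbour`` to ``node`` that
    does not use the edge between them; ``math.inf`` if no such path.
    """
    _require_adjacent(net, node, blocked_neighbour)
    indptr, indices = net.csr()
    path = _kernels.alternative_path(
        indptr, indices, int(blocked_neighbour), int(node), int(net.n_nodes)
    )
    return float(len(path)) if len(path) else math.inf


def simulate_block(
    net: SpatialNetwork,
    node: int,
    blocked_neighbour: int,
    cfg: DDMConfig,
) -> tuple[bool, np.ndarray | None]:
    """Run the DDM with unidirectional block on (blocked_neighbour -> node).

    Dynamics: discrete time; a node excited at step t excites all resting
    neighbours at t+1 and is then refractory, becoming re-excitable once
    tau steps have elapsed since its excitation.  One wavefront is paced
    from ``cfg.pacing``; transmission across the blocked edge is
    suppressed for its first arrival only.  Reentry is declared when the
    wavefront, having reached ``node`` by an alternative path, re-traverses
    the blocked site after the refractory period of ``blocked_neighbour``
    has elapsed, i.e. a self-sustaining loop has formed within the horizon.

    Returns ``(reentry, loop)`` with ``loop`` the node sequence of the
    reentrant circuit (from the activation-time predecessor graph) or
    ``None``.
    """
    _require_adjacent(net, node, blocked_neighbour)
    n = net.n_nodes
    indptr, indices = net.csr()
    horizon = cfg.horizon(n)

    if cfg.pacing == "block":
        sources = [int(blocked_neighbour)]
    else:
        sources = [int(s) for s in np.atleast_1d(np.asarray(cfg.pacing))]

    NEVER = -(10**9)
    last_exc = np.full(n, NEVER, dtype=np.int64)
    first_act = np.full(n, -1, dtype=np.int64)
    pred = np.full(n, -1, dtype=np.int64)

    current = []
    for s in sources:
        last_exc[s] = 0
        first_act[s] = 0
        current.append(s)
    block_spent = False

    t = 0
    while current and t < horizon:
        t += 1
        nxt = []
        for u in current:
            for k in range(indptr[u], indptr[u + 1]):
                w = int(indices[k])
                if u == blocked_neighbour and w == node and not block_spent:
                    block_spent = True  # first arrival suppressed
                    continue
                if t - last_exc[w] >= cfg.tau:
                    last_exc[w] = t
                    if first_act[w] < 0:
                        first_act[w] = t
                        pred[w] = u
                    nxt.append(w)
        current = nxt

    t_b = int(first_act[blocked_neighbour])
    t_n = int(first_act[node])
    if t_n < 0 or t_b < 0:
        if t_n < 0:
            logger.warning(
                "pacing source never reaches node %d; reentry trivially false",
                node,
            )
        return False, None

    return_time = t_n + 1 - t_b
    reentry = cfg.tau <= return_time <= horizon
    if not reentry:
        return False, None

    # loop from the predecessor chain node <- ... <- blocked_neighbour
    chain = [int(node)]
    u = int(node)
    while pred[u] >= 0 and u != blocked_neighbour:
        u = int(pred[u])
        chain.append(u)
    if chain[-1] != blocked_neighbour:
        return True, None  # paced elsewhere: no clean loop through the block
    return True, np.array(chain[::-1], dtype=np.int64)


def find_substrate(
    net: SpatialNetwork,
    cfg: DDMConfig,
    grid_shape: tuple[int, int, int] | None = None,
    circuits: object = "all",
    rng: np.random.Generator | None = None,
) -> SubstrateResult:
    """Evaluate conduction block at every (node, incoming-direction) pair.

    Under the uniform block rule each directed edge is one block
    opportunity; the result lists every pair whose block induces reentry
    (shortest return length between tau and the horizon), the reentrant
    circuits, and the per-voxel count of circuits touching each voxel.

    ``circuits`` controls circuit extraction: ``"all"`` records the loop
    of every inducing edge, ``"none"`` skips extraction (counts are then
    zero), an integer k samples k circuits uniformly with replacement
    among inducing (node, direction) pairs — the fixed-size sampling used
    for risk maps.
    """
    indptr, indices = net.csr()
    edges = net.edges
    horizon = cfg.horizon(net.n_nodes)
    if len(edges):
        lengths = _kernels.return_lengths(
            indptr,
            indices,
            np.ascontiguousarray(edges[:, 0]),
            np.ascontiguousarray(edges[:, 1]),
            int(horizon - 1),
        )
        inducing = (lengths >= cfg.tau) & (lengths > 0)
    else:
        lengths = np.empty(0, dtype=np.int64)
        inducing = np.zeros(0, dtype=bool)

    ind_edges = edges[inducing]
    ind_lengths = lengths[inducing]
    # both directions of an inducing edge are inducing (L is symmetric)
    pairs = (
        np.concatenate([ind_edges, ind_edges[:, ::-1]])
        if len(ind_edges)
        else np.empty((0, 2), dtype=np.int64)
    )
    substrate_nodes = np.unique(ind_edges) if len(ind_edges) else np.empty(0, np.int64)

    if grid_shape is None:
        grid_shape = tuple(net.voxels.max(axis=0) + 1) if net.n_nodes else (1, 1, 1)
    counts = np.zeros(grid_shape, dtype=np.int64)

    chosen: list[int] = []
    if len(ind_edges):
        if circuits == "all":
            chosen = list(range(len(ind_edges)))
        elif circuits == "none":
            chosen = []
        else:
            k = int(circuits)
            rng = rng if rng is not None else np.random.default_rng(0)
            chosen = list(rng.integers(0, len(ind_edges), size=k))

    circuit_list: list[Circuit] = []
    for e in chosen:
        b, t = int(ind_edges[e, 0]), int(ind_edges[e, 1])
        path = _kernels.alternative_path(indptr, indices, b, t, int(horizon - 1))
        if len(path) == 0:  # pragma: no cover - inducing implies a path
            continue
        circ = Circuit(nodes=path, length=len(path), blocked=(t, b))
        circuit_list.append(circ)
        vox = circ.voxel_set(net.voxels)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1

    return SubstrateResult(
        substrate_nodes=substrate_nodes,
        pairs=pairs,
        circuits=circuit_list,
        per_voxel_counts=counts,
        n_substrates=len(pairs),
        n_opportunities=2 * len(edges),
        tau=cfg.tau,
        provenance={
            "ddm": cfg,
            "return_lengths_max": int(lengths.max()) if len(lengths) else 0,
        },
    )


def _require_adjacent(net: SpatialNetwork, node: int, blocked_neighbour: int) -> None:
    indptr, indices = net.csr()
    neigh = indices[indptr[int(node)] : indptr[int(node) + 1]]
    if int(blocked_neighbour) not in neigh:
        raise ValueError(
            f"nodes {node} and {blocked_neighbour} are not adjacent"
        )
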