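"""Spatial-network construction from fibre tracts, plus the fibre-less null.

Two edge classes model the electrical coupling of myocardial tissue:

* longitudinal edges join consecutive nodes of the same fibre tract with
  probability 1 (gap junctions along a fibre are always present);
* transverse edges join nearby nodes of different tracts with a
  distance-dependent probability, the logistic

      p(x; r, c) = 1 / (exp(r (x - c)) + 1),

  where ``x`` is the node separation, ``r`` the steepness (7 by default)
  and ``c`` a characteristic coupling distance.  Reducing ``c`` removes
  transverse edges, mimicking the progressive accumulation of electrically
  insulating interstitial fibrosis.  Only node pairs with ``x < cutoff``
  (2 voxel units by default) are candidates.

The fibre-less null model keeps the geometry but drops fibre information:
nodes are scattered at ~1 per occupied voxel with a ``d_sep`` hard core and
*all* candidate pairs couple through p(x; r, c); there are no longitudinal
edges.

Transverse randomness uses one fixed uniform variate per candidate pair,
derived by hashing the pair identity with the seed.  Edge sets are
therefore *nested* in ``c``: raising ``c`` only ever adds edges, which
makes coupling sweeps directly comparable network-by-network.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit

from .geometry import VoxelGeometry
from .tractography import TractSet, _PointGrid, sample_seed_points

LONGITUDINAL = 0
TRANSVERSE = 1


@dataclass
class CouplingConfig:
    c: float = 1.0  # characteristic coupling distance, voxel units
    r: float = 7.0  # steepness of the logistic fall-off
    cutoff: float = 2.0  # candidate-pair distance bound, voxel units
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("r must be > 0")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")


def connection_probability(x, r: float = 7.0, c: float = 1.0):
    """Transverse coupling probability p(x; r, c) = 1/(e^{r(x-c)} + 1).

    Strictly decreasing in ``x``, equal to 1/2 exactly at ``x == c``.
    Accepts scalars or arrays; raises on negative distances.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    p = expit(-r * (x - c))
    return float(p) if p.ndim == 0 else p


def candidate_pairs(
    positions: np.ndarray, cutoff: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered node pairs with separation strictly below ``cutoff``.

    Returns ``(pairs, distances)`` with ``pairs`` an (m, 2) array of node
    indices (i < j), each pair exactly once.  Uses a k-d tree but is
    contractually identical to brute-force all-pairs enumeration.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    keep = d < cutoff  # query_pairs uses <=; the contract is strict
    pairs, d = pairs[keep], d[keep]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order].astype(np.int64), d[order]


def pair_uniforms(i: np.ndarray, j: np.ndarray, seed: int) -> np.ndarray:
    """One reproducible U(0,1) variate per unordered node pair.

    A splitmix64-style hash of (min, max, seed); independent of the order
    in which pairs are enumerated, so the same pair always sees the same
    uniform for a given seed.
    """
    lo = np.minimum(i, j).astype(np.uint64)
    hi = np.maximum(i, j).astype(np.uint64)
    seed_mix = np.uint64((int(seed) * 0xD6E8FEB86659FD93) % 2**64)
    x = (
        lo * np.uint64(0x9E3779B97F4A7C15)
        + hi * np.uint64(0xC2B2AE3D27D4EB4F)
        + seed_mix
    )
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return (x >> np.uint64(11)).astype(np.float64) * 2.0**-53


@dataclass
class SpatialNetwork:
    """Nodes with positions and home voxels; labelled undirected edges."""

    positions: np.ndarray  # (n, 3) voxel units
    voxels: np.ndarray  # (n, 3) integer home-voxel indices
    tract_ids: np.ndarray  # (n,) tract of each node, -1 for the null model
    edges: np.ndarray  # (e, 2) node pairs, i < j
    kinds: np.ndarray  # (e,) LONGITUDINAL or TRANSVERSE
    provenance: dict = dc_field(default_factory=dict)
    _csr: tuple | None = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.kinds = np.asarray(self.kinds, dtype=np.uint8).reshape(-1)
        if len(self.edges):
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            canon = np.sort(self.edges, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise ValueError("duplicate edges are not allowed")
            self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, kind: int | None = None) -> np.ndarray:
        sel = slice(None) if kind is None else self.kinds == kind
        e = self.edges[sel]
        return np.bincount(e.ravel(), minlength=self.n_nodes)

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected adjacency in CSR form (indptr, indices)."""
        if self._csr is None:
            src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            order = np.argsort(src, kind="stable")
            src, dst = src[order], dst[order]
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.add.at(indptr, src + 1, 1)
            np.cumsum(indptr, out=indptr)
            self._csr = (indptr, dst.astype(np.int64))
        return self._csr

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(i, pos=tuple(self.positions[i]), tract=int(self.tract_ids[i]))
        for (u, v), k in zip(self.edges, self.kinds):
            g.add_edge(
                int(u), int(v),
                kind="longitudinal" if k == LONGITUDINAL else "transverse",
            )
        return g

    def save_edgelist(self, path: str | Path) -> Path:
        """Plain-text node/edge tables: <stem>_nodes.csv and <stem>_edges.csv."""
        import pandas as pd

        path = Path(path)
        nodes = pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "vx": self.voxels[:, 0],
                "vy": self.voxels[:, 1],
                "vz": self.voxels[:, 2],
                "tract": self.tract_ids,
            }
        )
        edges = pd.DataFrame(
            {
                "u": self.edges[:, 0],
                "v": self.edges[:, 1],
                "kind": np.where(
                    self.kinds == LONGITUDINAL, "longitudinal", "transverse"
                ),
            }
        )
        nodes.to_csv(path.with_name(path.stem + "_nodes.csv"), index=False)
        edges.to_csv(path.with_name(path.stem + "_edges.csv"), index=False)
        return path

    def save_graphml(self, path: str | Path) -> Path:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))
        return Path(path)


class FibreCoupler:
    """Repeated fibre-network realisations over a fixed tract set.

    Node positions, longitudinal edges and candidate pairs depend only on
    the tracts, so they are computed once; each realisation only redraws
    the per-pair uniforms against the logistic coupling.
    """

    def __init__(self, tracts: TractSet, cutoff: float = 2.0):
        positions, tract_ids = tracts.node_table()
        if len(positions) == 0:
            raise ValueError("tract set has no node points")
        self.positions = positions
        self.tract_ids = tract_ids
        self.voxels = np.floor(positions).astype(np.int64)
        self.cutoff = cutoff

        # longitudinal: consecutive nodes along each tract (node_table order)
        same_tract = tract_ids[:-1] == tract_ids[1:]
        idx = np.arange(len(positions) - 1)[same_tract]
        self.long_edges = np.stack([idx, idx + 1], axis=1)

        pairs, dists = candidate_pairs(positions, cutoff)
        cross = tract_ids[pairs[:, 0]] != tract_ids[pairs[:, 1]]
        self.pairs, self.dists = pairs[cross], dists[cross]

    def network(self, cfg: CouplingConfig) -> SpatialNetwork:
        if cfg.cutoff != self.cutoff:
            raise ValueError("coupler was built with a different cutoff")
        u = pair_uniforms(self.pairs[:, 0], self.pairs[:, 1], cfg.seed)
        take = u < connection_probability(self.dists, cfg.r, cfg.c)
        trans_edges = self.pairs[take]
        kinds = np.concatenate(
            [
                np.full(len(self.long_edges), LONGITUDINAL, dtype=np.uint8),
                np.full(len(trans_edges), TRANSVERSE, dtype=np.uint8),
            ]
        )
        return SpatialNetwork(
            positions=self.positions,
            voxels=self.voxels,
            tract_ids=self.tract_ids,
            edges=np.concatenate([self.long_edges, trans_edges]),
            kinds=kinds,
            provenance={"builder": "fibre", "coupling": cfg},
        )


def build_fibre_network(
    tracts: TractSet,
    cfg: CouplingConfig,
    rng: np.random.Generator | None = None,
) -> SpatialNetwork:
    """Couple tract nodes into a spatial network.

    Consecutive nodes of the same tract are joined deterministically
    (longitudinal, p = 1).  Every candidate pair of nodes on *different*
    tracts gains a transverse edge with independent probability
    p(x; r, c); non-adjacent pairs on the same tract get no edge.
    Reproducible for a fixed ``cfg.seed``.
    """
    return FibreCoupler(tracts, cfg.cutoff).network(cfg)


class NullCoupler:
    """Repeated null-model realisations over one fixed node placement."""

    def __init__(
        self,
        geom: VoxelGeometry,
        d_sep: float = 0.7,
        cutoff: float = 2.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        positions = sample_seed_points(
            geom, d_sep, rng, n_max=geom.n_occupied, max_failures=2000
        )
        if len(positions) == 0:
            raise ValueError("could not place any nodes")
        self.positions = positions
        self.voxels = np.floor(positions).astype(np.int64)
        self.d_sep = d_sep
        self.cutoff = cutoff
        self.pairs, self.dists = candidate_pairs(positions, cutoff)

    def network(self, cfg: CouplingConfig) -> SpatialNetwork:
        if cfg.cutoff != self.cutoff:
            raise ValueError("coupler was built with a different cutoff")
        u = pair_uniforms(self.pairs[:, 0], self.pairs[:, 1], cfg.seed)
        take = u < connection_probability(self.dists, cfg.r, cfg.c)
        edges = self.pairs[take]
        return SpatialNetwork(
            positions=self.positions,
            voxels=self.voxels,
            tract_ids=np.full(len(self.positions), -1, dtype=np.int64),
            edges=edges,
            kinds=np.full(len(edges), TRANSVERSE, dtype=np.uint8),
            provenance={"builder": "null", "coupling": cfg, "d_sep": self.d_sep},
        )


def build_null_network(
    geom: VoxelGeometry,
    cfg: CouplingConfig,
    d_sep: float = 0.7,
    rng: np.random.Generator | None = None,
) -> SpatialNetwork:
    """Fibre-less null model on the same geometry.

    Nodes are placed uniformly at random at ~1 per occupied voxel, each
    accepted only if at least ``d_sep`` from all previously accepted nodes;
    every candidate pair (separation < cutoff) couples with probability
    p(x; r, c).  All edges are transverse; fibre orientation plays no role.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return NullCoupler(geom, d_sep, cfg.cutoff, rng).network(cfg)
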