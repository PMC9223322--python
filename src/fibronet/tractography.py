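"""Streamline tractography over a voxel fibre-orientation field.

A local axial orientation field says how fibres run at each voxel but not
how they chain together.  This module reconstructs global fibre tracts with
an evenly-spaced-streamlines (ESS) scheme: seed points are dropped with a
minimum separation ``d_sep``, streamlines are integrated forwards and
backwards along the field, and candidates are accepted longest-first while
keeping every accepted tract at least ``d_sep`` from the others.  Node
points are then placed at even arc-length intervals along each accepted
tract (one voxel by default) until the tract set carries roughly
``target_density`` nodes per occupied voxel, uniformly across the tissue.

Termination of a streamline follows standard ESS practice: leaving the
mask or hitting a voxel with no orientation, turning more than
``max_angle`` in a single step, approaching a previously accepted tract
closer than ``d_sep``, or exceeding a length bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .geometry import OrientationField, VoxelGeometry


@dataclass
class TractographyParams:
    d_sep: float = 0.7  # minimum seed/streamline separation, voxel units
    step: float = 0.5  # integration step, voxel units
    max_angle: float = math.pi / 3  # per-step turning limit, radians
    target_density: float = 1.0  # nodes per occupied voxel
    node_spacing: float = 1.0  # along-fibre node interval, voxel units
    seed: int = 0
    batch_size: int = 64  # candidate streamlines traced per round
    max_tract_len: float = 1000.0  # arc-length bound, voxel units
    max_seed_failures: int = 400  # consecutive rejections before giving up

    def __post_init__(self) -> None:
        if not self.d_sep > 0:
            raise ValueError("d_sep must be > 0")
        if not (0 < self.step <= 1):
            raise ValueError("step must be in (0, 1]")
        if not self.target_density > 0:
            raise ValueError("target_density must be > 0")


@dataclass
class FibreTract:
    """An ordered polyline with node points placed along it."""

    points: np.ndarray  # (m, 3) continuous coordinates, voxel units
    node_points: np.ndarray = dc_field(
        default_factory=lambda: np.empty((0, 3))
    )
    round_index: int = 0

    @property
    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(
            np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum()
        )


@dataclass
class TractSet:
    tracts: list[FibreTract]
    provenance: dict

    @property
    def n_nodes(self) -> int:
        return sum(len(t.node_points) for t in self.tracts)

    def node_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All node points and their tract ids, in tract/along-tract order."""
        if not self.tracts:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        pos = np.concatenate([t.node_points for t in self.tracts])
        tid = np.concatenate(
            [np.full(len(t.node_points), i) for i, t in enumerate(self.tracts)]
        )
        return pos, tid


def save_tracts_csv(tracts: TractSet, path) -> None:
    """Write tract polylines as a CSV of point sequences.

    Columns: tract id, point index along the tract, x, y, z (voxel
    units), and whether the row is a node point.
    """
    import pandas as pd

    rows = []
    for tid, tract in enumerate(tracts.tracts):
        nodes = {tuple(np.round(p, 9)) for p in np.atleast_2d(tract.node_points)}
        for k, p in enumerate(np.atleast_2d(tract.points)):
            rows.append(
                {
                    "tract": tid,
                    "index": k,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                    "is_node": tuple(np.round(p, 9)) in nodes,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


class _PointGrid:
    """Uniform spatial hash supporting 'any accepted point within d?'."""

    def __init__(self, d: float):
        self.d = d
        self.d2 = d * d
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p) -> tuple[int, int, int]:
        return (int(p[0] // self.d), int(p[1] // self.d), int(p[2] // self.d))

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(self._key(p), []).append(np.asarray(p, dtype=float))

    def add_many(self, pts: np.ndarray) -> None:
        for p in pts:
            self.add(p)

    def near(self, p) -> bool:
        kx, ky, kz = self._key(p)
        px, py, pz = float(p[0]), float(p[1]), float(p[2])
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.cells.get((kx + dx, ky + dy, kz + dz), ()):
                        if (
                            (px - q[0]) ** 2
                            + (py - q[1]) ** 2
                            + (pz - q[2]) ** 2
                        ) < self.d2:
                            return True
        return False


def sample_seed_points(
    geom: VoxelGeometry,
    d_sep: float,
    rng: np.random.Generator,
    n_max: int | None = None,
    existing: _PointGrid | None = None,
    max_failures: int = 400,
) -> np.ndarray:
    """Random points in occupied voxels, pairwise at least ``d_sep`` apart.

    Sequential rejection sampling: proposals are drawn uniformly inside
    random occupied voxels and accepted if no previously accepted point
    (including any ``existing`` exclusion set) lies within ``d_sep``.
    Sampling stops after ``n_max`` acceptances or ``max_failures``
    consecutive rejections.
    """
    occ = geom.occupied_indices()
    if len(occ) == 0:
        raise ValueError("geometry has no occupied voxels")
    grid = _PointGrid(d_sep)  # batch-local; `existing` is never mutated
    accepted: list[np.ndarray] = []
    failures = 0
    while failures < max_failures and (n_max is None or len(accepted) < n_max):
        voxel = occ[rng.integers(len(occ))]
        p = voxel + rng.random(3)
        if grid.near(p) or (existing is not None and existing.near(p)):
            failures += 1
            continue
        grid.add(p)
        accepted.append(p)
        failures = 0
    return np.array(accepted) if accepted else np.empty((0, 3))


def _orientation_at(
    pos: np.ndarray, field: OrientationField, geom: VoxelGeometry
) -> np.ndarray | None:
    """Nearest-voxel orientation lookup; None outside the mask or missing."""
    idx = np.floor(pos).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(geom.shape)):
        return None
    if not geom.mask[idx[0], idx[1], idx[2]]:
        return None
    v = field.vectors[idx[0], idx[1], idx[2]]
    if not np.all(np.isfinite(v)):
        return None
    return v


def trace_tract(
    seed: np.ndarray,
    field: OrientationField,
    geom: VoxelGeometry,
    params: TractographyParams,
    avoid: _PointGrid | None = None,
) -> FibreTract:
    """Integrate a streamline bidirectionally from ``seed``.

    Fixed-step integration with nearest-voxel orientation lookup and sign
    continuity: at each step the sign of the axial vector minimizing the
    turning angle with the previous direction is chosen.  The forward and
    backward halves are concatenated into one polyline.

    Raises
    ------
    ValueError
        If the orientation is missing at the seed voxel.
    """
    seed = np.asarray(seed, dtype=float)
    v0 = _orientation_at(seed, field, geom)
    if v0 is None:
        raise ValueError(f"no orientation at seed {seed}")

    half_len = params.max_tract_len / 2.0

    def march(direction: np.ndarray) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        pos = seed.copy()
        d = direction.copy()
        travelled = 0.0
        cos_cap = math.cos(params.max_angle)
        while travelled < half_len:
            nxt = pos + params.step * d
            v = _orientation_at(nxt, field, geom)
            if v is None:  # left the mask / missing orientation
                break
            dot = float(np.dot(v, d))
            v_step = v if dot >= 0 else -v
            if abs(dot) < cos_cap:  # turning more than max_angle
                break
            if avoid is not None and avoid.near(nxt):
                break
            pts.append(nxt)
            pos = nxt
            d = v_step
            travelled += params.step
        return pts

    fwd = march(v0)
    bwd = march(-v0)
    points = list(reversed(bwd)) + [seed] + fwd
    return FibreTract(points=np.array(points))


def place_nodes(
    tract: FibreTract,
    node_spacing: float,
    phase: float,
    geom: VoxelGeometry | None = None,
) -> np.ndarray:
    """Place node points at even arc-length intervals along a tract.

    The first node sits at arc position ``phase * node_spacing`` (a random
    phase keeps node lattices from aligning between tracts); subsequent
    nodes follow every ``node_spacing`` units along the polyline.
    """
    pts = tract.points
    if len(pts) < 2:
        return np.empty((0, 3))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(phase * node_spacing, total + 1e-12, node_spacing)
    if len(targets) == 0:
        return np.empty((0, 3))
    idx = np.clip(np.searchsorted(s, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - s[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    nodes = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    if geom is not None:
        nodes = nodes[geom.contains(nodes)]
    tract.node_points = nodes
    return nodes


def generate_tract_set(
    geom: VoxelGeometry,
    field: OrientationField,
    params: TractographyParams | None = None,
    rng: np.random.Generator | None = None,
) -> TractSet:
    """Cover the tissue with tracts and node points at the target density.

    Rounds of candidate streamlines are traced from admissible seed pools;
    within each round candidates are accepted in decreasing length order,
    discarding any whose points come within ``d_sep`` of a tract accepted
    earlier.  Rounds repeat until the node count reaches
    ``target_density x occupied voxels`` or no admissible seeds remain.
    """
    params = params or TractographyParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    capacity = int(round(params.target_density * geom.n_occupied))
    avoid = _PointGrid(params.d_sep)
    tracts: list[FibreTract] = []
    n_nodes = 0
    round_index = 0
    barren_rounds = 0
    while n_nodes < capacity:
        seeds = sample_seed_points(
            geom,
            params.d_sep,
            rng,
            n_max=params.batch_size,
            existing=avoid,
            max_failures=params.max_seed_failures,
        )
        if len(seeds) == 0:
            break
        candidates = []
        for seed in seeds:
            try:
                tract = trace_tract(seed, field, geom, params, avoid=avoid)
            except ValueError:
                continue
            if len(tract.points) >= 2:
                candidates.append(tract)
        candidates.sort(key=lambda t: t.arc_length, reverse=True)
        accepted_any = False
        for tract in candidates:
            if any(avoid.near(p) for p in tract.points):
                continue  # conflicts with a tract accepted this round
            tract.round_index = round_index
            avoid.add_many(tract.points)
            place_nodes(tract, params.node_spacing, float(rng.random()), geom)
            tracts.append(tract)
            n_nodes += len(tract.node_points)
            accepted_any = True
            if n_nodes >= capacity:
                break
        if accepted_any:
            barren_rounds = 0
        else:
            barren_rounds += 1
            if barren_rounds >= 5 or len(seeds) < params.batch_size:
                break  # seed pool effectively exhausted
        round_index += 1
    return TractSet(
        tracts=tracts,
        provenance={
            "params": params,
            "seed": params.seed,
            "rounds": round_index + 1,
            "capacity": capacity,
        },
    )
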