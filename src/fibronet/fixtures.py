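"""Seeded synthetic tissue geometries with prescribed fibre fields.

Real atrial fibre maps are large, hard to obtain, and individual-specific.
These fixtures emulate the structural features that matter for the method —
thin convex walls, pectinate-muscle-like ridges, pulmonary-vein-like
sleeves, fibre-disarray patches, and small structural holes — on grids
small enough that the whole pipeline runs in seconds.  Every fixture is
deterministic for a fixed seed.

Fixture kinds
-------------
slab
    Rectangular plate of constant thickness with a uniform in-plane fibre
    angle; the baseline geometry for density and coupling checks.
wedge
    Plate whose thickness grows linearly along y, giving a built-in
    gradient of the occupied voxel fraction for thickness-bias tests.
ridge
    Half-cylinder attached to a plate, a pectinate-muscle analogue, with
    fibres along the ridge axis.
sleeve
    Hollow tube joined to a plate, a pulmonary-vein analogue, with
    circumferential fibres on the tube by default.

Disarray regions resample fibre vectors from a von Mises-Fisher
distribution about the base direction with concentration kappa (small
kappa = strong disarray); holes carve spheres out of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import vonmises_fisher

from .geometry import OrientationField, VoxelGeometry


@dataclass
class DisarrayRegion:
    """Axis-aligned box [lo, hi) with a von Mises-Fisher concentration."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    kappa: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")


@dataclass
class FixtureSpec:
    kind: str  # slab | wedge | ridge | sleeve
    dims: tuple[int, int, int]
    thickness: int = 4
    thickness_min: int = 1  # wedge: thickness at the thin (y=0) end
    ridge_radius: float = 4.0
    sleeve_radius: float = 6.0
    sleeve_wall: float = 2.0
    sleeve_height: int = 0  # 0 -> fill the grid above the plate
    fibre_angle: float = 0.0  # in-plane angle, radians
    disarray: list[DisarrayRegion] = dc_field(default_factory=list)
    holes: list[tuple[tuple[float, float, float], float]] = dc_field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "wedge", "ridge", "sleeve"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be positive, got {self.dims}")
        if not (1 <= self.thickness <= self.dims[2]):
            raise ValueError("thickness must be within the z dimension")
        if self.kind == "wedge" and not (
            1 <= self.thickness_min <= self.thickness
        ):
            raise ValueError("wedge needs 1 <= thickness_min <= thickness")
        if any(r < 0 for _, r in self.holes):
            raise ValueError("hole radii must be >= 0")


def make_fixture(spec: FixtureSpec) -> tuple[VoxelGeometry, OrientationField]:
    """Build the geometry and fibre field described by ``spec``.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.dims
    mask = np.zeros(spec.dims, dtype=bool)
    vectors = np.full(spec.dims + (3,), np.nan)
    a = spec.fibre_angle
    base = np.array([np.cos(a), np.sin(a), 0.0])

    if spec.kind == "slab":
        mask[:, :, : spec.thickness] = True
        vectors[mask] = base
    elif spec.kind == "wedge":
        t = np.rint(
            np.linspace(spec.thickness_min, spec.thickness, ny)
        ).astype(int)
        for j in range(ny):
            mask[:, j, : t[j]] = True
        vectors[mask] = base
    elif spec.kind == "ridge":
        mask[:, :, : spec.thickness] = True
        yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
        y0 = (ny - 1) / 2.0
        ridge = (yy - y0) ** 2 + (zz - (spec.thickness - 1)) ** 2 <= spec.ridge_radius**2
        mask |= ridge[None, :, :]
        vectors[mask] = np.array([1.0, 0.0, 0.0])  # fibres along ridge axis
    elif spec.kind == "sleeve":
        mask[:, :, : spec.thickness] = True
        vectors[mask] = base
        x0, y0 = (nx - 1) / 2.0, (ny - 1) / 2.0
        zt = nz if spec.sleeve_height == 0 else min(nz, spec.thickness + spec.sleeve_height)
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        rr = np.hypot(xx - x0, yy - y0)
        ring = (rr <= spec.sleeve_radius) & (rr >= spec.sleeve_radius - spec.sleeve_wall)
        inner = rr < spec.sleeve_radius - spec.sleeve_wall
        for k in range(spec.thickness, zt):
            mask[:, :, k] = ring
        # open the lumen through the plate so the tube is hollow end-to-end
        for k in range(spec.thickness):
            mask[inner, k] = False
        # circumferential fibres on the tube
        theta = np.arctan2(yy - y0, xx - x0)
        tang = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
        for k in range(spec.thickness, zt):
            vectors[:, :, k][ring] = tang[ring]

    for centre, radius in spec.holes:
        cx, cy, cz = centre
        xs, ys, zs = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        sphere = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= radius**2
        mask[sphere] = False
        vectors[sphere] = np.nan

    for region in spec.disarray:
        box = np.zeros(spec.dims, dtype=bool)
        box[
            region.lo[0] : region.hi[0],
            region.lo[1] : region.hi[1],
            region.lo[2] : region.hi[2],
        ] = True
        sel = box & mask & np.all(np.isfinite(vectors), axis=-1)
        idx = np.argwhere(sel)
        for ijk in idx:
            mu = vectors[tuple(ijk)]
            v = np.asarray(
                vonmises_fisher(mu, region.kappa).rvs(1, random_state=rng),
                dtype=float,
            ).reshape(3)
            vectors[tuple(ijk)] = _axialize(v)

    geom = VoxelGeometry(mask)
    return geom, OrientationField.from_vectors(vectors, geom)


def _axialize(v: np.ndarray) -> np.ndarray:
    """Canonical sign for an axial vector (first nonzero component > 0)."""
    for comp in v:
        if comp != 0:
            return v if comp > 0 else -v
    return v


def fixture_suite(seed: int = 0) -> dict[str, tuple[VoxelGeometry, OrientationField]]:
    """The canonical named test set used across the package's test suite."""
    specs = {
        "thin_slab": FixtureSpec("slab", (40, 30, 2), thickness=2, seed=seed),
        "thick_slab": FixtureSpec("slab", (40, 30, 8), thickness=8, seed=seed),
        "wedge": FixtureSpec(
            "wedge", (60, 40, 8), thickness=8, thickness_min=1, seed=seed
        ),
        "ridge": FixtureSpec(
            "ridge", (60, 40, 8), thickness=3, ridge_radius=4.0, seed=seed
        ),
        "sleeve": FixtureSpec(
            "sleeve", (40, 40, 16), thickness=3, sleeve_radius=8.0, seed=seed
        ),
        "slab_disarray": FixtureSpec(
            "slab",
            (60, 40, 4),
            thickness=4,
            disarray=[DisarrayRegion((20, 0, 0), (40, 40, 4), kappa=3.0)],
            seed=seed,
        ),
        "slab_holes": FixtureSpec(
            "slab",
            (40, 30, 4),
            thickness=4,
            holes=[((12.0, 15.0, 1.5), 3.0), ((28.0, 15.0, 1.5), 3.0)],
            seed=seed,
        ),
    }
    return {name: make_fixture(s) for name, s in specs.items()}
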