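"""Voxel geometries and axial fibre-orientation fields.

The spatial canvas for the whole pipeline is a 3-d boolean occupancy mask
(``True`` = tissue) together with a per-occupied-voxel *axial* unit vector
giving the local fibre orientation.  Axial means sign-free: ``v`` and ``-v``
denote the same orientation, so all averaging goes through the structure
tensor (mean outer product) rather than the vector mean, which would vanish
for antiparallel fibres.

All distances downstream are expressed in voxel units (1.0 = one voxel
edge); the physical ``spacing`` (micrometres) is carried only as metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometry or orientation-field input."""


@dataclass
class VoxelGeometry:
    """3-d occupancy mask with voxel spacing.

    Parameters
    ----------
    mask : ndarray of bool, shape (nx, ny, nz)
        True where the voxel is tissue.
    spacing : float
        Physical edge length of a voxel in micrometres.  Informational
        only; every distance elsewhere in the package is in voxel units.
    origin : ndarray of float, shape (3,)
        Physical coordinate of voxel (0, 0, 0).
    """

    mask: np.ndarray
    spacing: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or min(self.mask.shape) < 1:
            raise GeometryError(
                f"mask must be 3-d with all dims >= 1, got shape {self.mask.shape}"
            )
        if not self.spacing > 0:
            raise GeometryError(f"spacing must be > 0, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_occupied(self) -> int:
        return int(self.mask.sum())

    def occupied_indices(self) -> np.ndarray:
        """Integer indices of occupied voxels, shape (n, 3)."""
        return np.argwhere(self.mask)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether continuous points (voxel units) fall in occupied voxels."""
        pts = np.atleast_2d(points)
        idx = np.floor(pts).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        ii = idx[inside]
        out[inside] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out if points.ndim > 1 else out[0]


@dataclass
class OrientationField:
    """Per-occupied-voxel axial unit vectors.

    ``vectors`` has shape ``mask.shape + (3,)``; entries are unit vectors at
    occupied voxels or NaN where the orientation is missing (and everywhere
    the mask is False).  The field is axial: v and -v are identical.
    """

    vectors: np.ndarray
    axial: bool = True

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise GeometryError(
                f"vectors must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )

    @classmethod
    def from_vectors(
        cls, vectors: np.ndarray, geom: VoxelGeometry, *, renormalize: bool = True
    ) -> "OrientationField":
        """Validate vectors against a geometry, blank unoccupied voxels.

        Raises
        ------
        GeometryError
            On shape mismatch, or zero-length vectors at occupied voxels
            (reported with their voxel indices).
        """
        vectors = np.asarray(vectors, dtype=float)
        if vectors.shape != geom.shape + (3,):
            raise GeometryError(
                f"vector grid shape {vectors.shape[:3]} does not match "
                f"mask shape {geom.shape}"
            )
        out = np.full_like(vectors, np.nan)
        occ = geom.mask
        v = vectors[occ]
        norms = np.linalg.norm(v, axis=1)
        finite = np.isfinite(norms)
        zero = finite & (norms == 0.0)
        if zero.any():
            bad = geom.occupied_indices()[zero]
            listing = ", ".join(str(tuple(int(x) for x in row)) for row in bad[:10])
            raise GeometryError(
                "zero-length orientation vectors at occupied voxels: "
                + listing
                + ("..." if len(bad) > 10 else "")
            )
        good = finite & (norms > 0)
        if renormalize:
            v = np.where(good[:, None], v / np.where(good, norms, 1.0)[:, None], np.nan)
        out[occ] = v
        return cls(out)

    def defined(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Boolean grid: True where an orientation vector is present."""
        d = np.all(np.isfinite(self.vectors), axis=-1)
        return d if mask is None else d & mask

    def at_voxel(self, ijk) -> np.ndarray:
        return self.vectors[tuple(ijk)]

    def check_unit(self, geom: VoxelGeometry) -> None:
        occ = self.defined(geom.mask)
        norms = np.linalg.norm(self.vectors[occ], axis=1)
        if occ.any() and np.abs(norms - 1.0).max() > _NORM_TOL:
            raise GeometryError("orientation vectors are not unit length")


# ---------------------------------------------------------------------------
# I/O: native .npz archive and NIfTI (via nibabel)
# ---------------------------------------------------------------------------

def save_geometry(
    path: str | Path,
    geom: VoxelGeometry,
    field: OrientationField | None = None,
) -> Path:
    """Write a geometry (and optional orientation field) to disk.

    ``.npz`` suffix writes the native archive (mask as uint8, vectors as
    float64, spacing, origin) and round-trips bit-exactly.  ``.nii`` /
    ``.nii.gz`` writes the mask as an integer NIfTI volume; the vectors go
    to a companion ``<stem>_vectors.nii[.gz]`` 4-d volume with a matching
    affine.
    """
    path = Path(path)
    if path.name.endswith(".npz"):
        payload = {
            "mask": geom.mask.astype(np.uint8),
            "spacing": np.float64(geom.spacing),
            "origin": geom.origin,
        }
        if field is not None:
            payload["vectors"] = field.vectors
        np.savez_compressed(path, **payload)
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([geom.spacing] * 3 + [1.0])
        affine[:3, 3] = geom.origin
        nib.save(nib.Nifti1Image(geom.mask.astype(np.uint8), affine), str(path))
        if field is not None:
            vpath = _vector_companion(path)
            nib.save(nib.Nifti1Image(field.vectors, affine), str(vpath))
        return path
    raise GeometryError(f"unsupported container suffix: {path.name}")


def load_geometry(
    path: str | Path, format: str | None = None
) -> tuple[VoxelGeometry, OrientationField | None]:
    """Load a geometry and, if present, its orientation field.

    The format is inferred from the suffix unless given explicitly
    (``"npz"`` or ``"nifti"``).  Orientation vectors are renormalized to
    unit length; vectors at unoccupied voxels are discarded.  A mask-only
    file returns ``(geometry, None)`` — usable by the fibre-less null model.
    """
    path = Path(path)
    if not path.exists():
        raise GeometryError(f"no such file: {path}")
    fmt = format or ("npz" if path.name.endswith(".npz") else "nifti")
    if fmt == "npz":
        with np.load(path) as z:
            geom = VoxelGeometry(
                mask=z["mask"].astype(bool),
                spacing=float(z["spacing"]),
                origin=z["origin"],
            )
            field = None
            if "vectors" in z:
                field = OrientationField.from_vectors(z["vectors"], geom)
        return geom, field
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = float(np.abs(affine[0, 0])) or 1.0
        geom = VoxelGeometry(
            mask=np.asarray(img.dataobj).astype(bool),
            spacing=spacing,
            origin=affine[:3, 3],
        )
        vpath = _vector_companion(path)
        field = None
        if vpath.exists():
            vimg = nib.load(str(vpath))
            field = OrientationField.from_vectors(
                np.asarray(vimg.dataobj, dtype=float), geom
            )
        return geom, field
    raise GeometryError(f"unknown format {fmt!r}")


def _vector_companion(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_vectors" + suf)
    raise GeometryError(f"not a NIfTI path: {path}")


# ---------------------------------------------------------------------------
# Coarse graining
# ---------------------------------------------------------------------------

def coarse_grain_field(
    geom: VoxelGeometry, field: OrientationField | None, factor: int
) -> tuple[VoxelGeometry, OrientationField | None]:
    """Aggregate geometry and orientation by an integer factor.

    An output voxel is occupied iff at least half of its (within-grid)
    child voxels are occupied, ties counting as occupied — a conservative
    rule that preserves thin walls.  The output orientation is the
    principal eigenvector of the mean outer product (structure tensor) of
    the child vectors, which is invariant to the sign of each child vector.
    Output spacing is ``factor`` times the input spacing.
    """
    if int(factor) != factor or factor < 1:
        raise GeometryError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return geom, field

    nx, ny, nz = geom.shape
    out_shape = tuple(-(-d // factor) for d in (nx, ny, nz))
    pad = [(0, o * factor - d) for o, d in zip(out_shape, (nx, ny, nz))]

    m = np.pad(geom.mask, pad, constant_values=False)
    blocks = m.reshape(
        out_shape[0], factor, out_shape[1], factor, out_shape[2], factor
    )
    child_occ = blocks.sum(axis=(1, 3, 5))
    # number of real (within-grid) children per block
    ones = np.pad(np.ones(geom.shape, dtype=int), pad, constant_values=0)
    child_n = ones.reshape(
        out_shape[0], factor, out_shape[1], factor, out_shape[2], factor
    ).sum(axis=(1, 3, 5))
    out_mask = (2 * child_occ >= child_n) & (child_n > 0) & (child_occ > 0)
    out_geom = VoxelGeometry(out_mask, spacing=geom.spacing * factor, origin=geom.origin)

    if field is None:
        return out_geom, None

    v = np.where(
        field.defined(geom.mask)[..., None], np.nan_to_num(field.vectors), 0.0
    )
    v = np.pad(v, pad + [(0, 0)], constant_values=0.0)
    vb = v.reshape(
        out_shape[0], factor, out_shape[1], factor, out_shape[2], factor, 3
    )
    # structure tensor sum over children: T_ab = sum_k v_a v_b
    tensors = np.einsum("ifjgkha,ifjgkhb->ijkab", vb, vb)
    counts = np.linalg.norm(vb, axis=-1).round().astype(int).sum(axis=(1, 3, 5))

    out_vectors = np.full(out_shape + (3,), np.nan)
    for i, j, k in np.argwhere(out_mask):
        if counts[i, j, k] == 0:
            logger.warning(
                "coarse_grain_field: no orientation data for occupied output "
                "voxel %s; flagged missing", (i, j, k)
            )
            continue
        out_vectors[i, j, k] = _principal_orientation(tensors[i, j, k])
    return out_geom, OrientationField(out_vectors)


def _principal_orientation(tensor: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Principal eigenvector of a 3x3 structure tensor, sign-canonical.

    Degenerate top eigenspace: pick the lexicographically smallest of the
    canonicalized eigenvectors spanning it, and warn.
    """
    w, vecs = np.linalg.eigh(tensor)
    top = w[-1]
    tied = np.nonzero(w >= top - tol * max(top, 1.0))[0]
    candidates = [_canonical_sign(vecs[:, i]) for i in tied]
    if len(candidates) > 1:
        logger.warning("degenerate structure tensor; breaking tie lexicographically")
        candidates.sort(key=tuple)
    v = candidates[0]
    return v / np.linalg.norm(v)


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Fix the arbitrary sign of an axial vector: first nonzero entry > 0."""
    for comp in v:
        if abs(comp) > 0:
            return v if comp > 0 else -v
    return v


def axial_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two axial orientations, in [0, pi/2]."""
    c = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, c))
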