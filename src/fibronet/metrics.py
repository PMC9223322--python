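"""Structural measures: OVF, LCF, cluster counts, risk-weighted histograms.

Occupied voxel fraction (OVF)
    Wall thickness is ill-defined in the tissue bulk, so the OVF stands in
    for it: the fraction of the lattice sphere of radius r_tilde (5 voxels
    by default) around a voxel that is occupied by tissue.  Thick walls
    read near 1, thin or convex regions read low.  The denominator is the
    full lattice sphere regardless of position — voxels beyond the grid
    edge count as empty — so boundary voxels genuinely read as low OVF.

Longitudinal connection fraction (LCF)
    Per node, the fraction of its edges that are longitudinal; per voxel,
    the mean over resident nodes.  A proxy for local fibre alignment:
    well-aligned regions keep most of their coupling along fibres.  It is
    undefined for the fibre-less null model (which has no longitudinal
    edges); label null-model voxels with the paired fibre-model LCF when a
    comparison is needed.

Cluster counts
    How spatially confined the substrate is: voxels containing identified
    circuits are sampled to a fixed size and clustered with DBSCAN at
    range ``eps`` (10 voxels by default) and minimum cluster size 1 —
    degenerating to single-linkage connected components — with a
    bootstrap over resamples for error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from sklearn.cluster import DBSCAN

from .geometry import VoxelGeometry
from .network import LONGITUDINAL, SpatialNetwork
from .risk import RiskMap


@dataclass
class MetricsConfig:
    r_tilde: float = 5.0  # OVF sphere radius, voxel units
    eps: float = 10.0  # DBSCAN clustering distance, voxel units
    min_cluster_size: int = 1
    n_sampled_voxels: int = 1000
    n_bootstrap: int = 100
    bin_width: float = 0.02  # OVF/LCF histogram bin width

    def __post_init__(self) -> None:
        if not self.r_tilde > 0:
            raise ValueError("r_tilde must be > 0")
        if not self.eps > 0:
            raise ValueError("eps must be > 0")
        if self.n_sampled_voxels < 1:
            raise ValueError("n_sampled_voxels must be >= 1")


def sphere_offsets(r_tilde: float) -> np.ndarray:
    """Integer offsets with centre distance <= r_tilde, shape (k, 3)."""
    r = int(np.floor(r_tilde))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = dx**2 + dy**2 + dz**2 <= r_tilde**2
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


def occupied_voxel_fraction(
    geom: VoxelGeometry, r_tilde: float = 5.0
) -> np.ndarray:
    """Per-voxel OVF map; NaN at unoccupied voxels.

    OVF(v) = (occupied voxels within distance r_tilde of v) / (all lattice
    voxels within r_tilde).  The denominator is position-independent and
    the grid is padded as empty, so values lie in (0, 1].
    """
    if not r_tilde > 0:
        raise ValueError("r_tilde must be > 0")
    offs = sphere_offsets(r_tilde)
    r = int(np.floor(r_tilde))
    size = 2 * r + 1
    kernel = np.zeros((size, size, size))
    kernel[offs[:, 0] + r, offs[:, 1] + r, offs[:, 2] + r] = 1.0
    counts = ndimage.convolve(
        geom.mask.astype(float), kernel, mode="constant", cval=0.0
    )
    ovf = counts / len(offs)
    out = np.where(geom.mask, ovf, np.nan)
    return out


def longitudinal_connection_fraction(
    net: SpatialNetwork, grid_shape: tuple[int, int, int] | None = None
) -> np.ndarray:
    """Per-voxel LCF map on the node home-voxel grid; NaN where undefined.

    Raises
    ------
    ValueError
        For a null-model network: the LCF is only defined when
        longitudinal edges exist.  Label null voxels with the paired
        fibre-model LCF map instead.
    """
    if np.all(net.tract_ids < 0):
        raise ValueError(
            "LCF is not defined for the fibre-less null model; use the "
            "paired fibre-model LCF to label null-model voxels"
        )
    deg = net.degree()
    ldeg = net.degree(kind=LONGITUDINAL)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(deg > 0, ldeg / np.maximum(deg, 1), np.nan)
    shape = grid_shape if grid_shape is not None else tuple(net.voxels.max(axis=0) + 1)
    total = np.zeros(shape)
    n = np.zeros(shape)
    ok = deg > 0
    vox = net.voxels[ok]
    np.add.at(total, (vox[:, 0], vox[:, 1], vox[:, 2]), frac[ok])
    np.add.at(n, (vox[:, 0], vox[:, 1], vox[:, 2]), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return out


def node_lcf(net: SpatialNetwork) -> np.ndarray:
    """Per-node longitudinal fraction (NaN for isolated nodes)."""
    deg = net.degree()
    ldeg = net.degree(kind=LONGITUDINAL)
    return np.where(deg > 0, ldeg / np.maximum(deg, 1), np.nan)


@dataclass
class ClusterCount:
    n_clusters: int  # from the primary sample
    interval: tuple[float, float]  # bootstrap percentile interval (2.5, 97.5)
    bootstrap_mean: float
    bootstrap_counts: np.ndarray


def cluster_count(points: np.ndarray, eps: float) -> int:
    """Number of DBSCAN clusters at range eps with minimum size 1.

    With min_samples = 1 every point belongs to a cluster and the labels
    are the connected components of the eps-neighbourhood graph.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty point set")
    labels = DBSCAN(eps=eps, min_samples=1).fit(points).labels_
    return int(labels.max()) + 1


def substrate_cluster_count(
    substrate_voxels: np.ndarray,
    cfg: MetricsConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterCount:
    """Spatial cluster count of the identified substrate, with bootstrap.

    ``n_sampled_voxels`` voxels are drawn from the substrate voxel set —
    without replacement when the set is at least that large (so a fully
    dispersed substrate yields one cluster per sampled voxel), with
    replacement otherwise (keeping the sample size fixed for small
    substrates) — and clustered with DBSCAN.  The bootstrap repeats the
    draw ``n_bootstrap`` times for the error bar.
    """
    cfg = cfg or MetricsConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    voxels = np.asarray(substrate_voxels, dtype=float)
    if voxels.ndim != 2 or len(voxels) == 0:
        raise ValueError("substrate voxel set must be a non-empty (m, 3) array")

    def draw() -> np.ndarray:
        k = cfg.n_sampled_voxels
        replace = len(voxels) < k
        idx = rng.choice(len(voxels), size=k, replace=replace)
        return voxels[idx]

    primary = cluster_count(draw(), cfg.eps)
    boots = np.array(
        [cluster_count(draw(), cfg.eps) for _ in range(cfg.n_bootstrap)]
    )
    lo, hi = (
        np.percentile(boots, [2.5, 97.5]) if len(boots) else (primary, primary)
    )
    return ClusterCount(
        n_clusters=primary,
        interval=(float(lo), float(hi)),
        bootstrap_mean=float(boots.mean()) if len(boots) else float(primary),
        bootstrap_counts=boots,
    )


def ensemble_cluster_count(
    member_voxel_sets: list,
    cfg: MetricsConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterCount:
    """Mean per-network substrate cluster count over an ensemble.

    The confinement of the substrate is a per-realisation property: each
    member's detected voxel set is sampled and clustered separately and
    the counts are averaged (pooling members first would blur isolated
    pockets into uniform coverage).  The interval is a bootstrap over
    ensemble members of that mean.
    """
    cfg = cfg or MetricsConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    per_member = []
    for voxels in member_voxel_sets:
        voxels = np.asarray(voxels, dtype=float)
        if len(voxels) == 0:
            continue
        k = cfg.n_sampled_voxels
        idx = rng.choice(len(voxels), size=k, replace=len(voxels) < k)
        per_member.append(cluster_count(voxels[idx], cfg.eps))
    if not per_member:
        raise ValueError("no ensemble member has a non-empty substrate")
    per_member = np.array(per_member, dtype=float)
    boots = np.array(
        [
            per_member[rng.integers(0, len(per_member), len(per_member))].mean()
            for _ in range(cfg.n_bootstrap)
        ]
    )
    lo, hi = (
        np.percentile(boots, [2.5, 97.5])
        if len(boots)
        else (per_member.mean(), per_member.mean())
    )
    return ClusterCount(
        n_clusters=int(round(per_member.mean())),
        interval=(float(lo), float(hi)),
        bootstrap_mean=float(per_member.mean()),
        bootstrap_counts=per_member,
    )


@dataclass
class RiskWeightedDistribution:
    ovf_edges: np.ndarray
    lcf_edges: np.ndarray | None
    counts: np.ndarray  # voxels per bin (unweighted)
    weighted: np.ndarray  # sum of local risk per bin
    weighted_mean: tuple  # (mean OVF, mean LCF or None) under risk weights
    percentiles: dict  # axis -> {10, 25, 50, 75, 90} risk-weighted
    substrate_mean_ovf: float  # mean OVF over voxels with detected circuits
    geometry_mean_ovf: float  # mean OVF over all occupied voxels


def _weighted_percentiles(x: np.ndarray, w: np.ndarray, qs) -> dict:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return {q: float(np.interp(q / 100.0, cw, x)) for q in qs}


def risk_weighted_distribution(
    risk: RiskMap,
    ovf: np.ndarray,
    lcf: np.ndarray | None = None,
    bin_width: float = 0.02,
) -> RiskWeightedDistribution:
    """Joint (OVF, LCF) distribution of voxels, risk-weighted and not.

    The unweighted histogram counts occupied voxels per bin; the weighted
    one sums local risk R_v per bin.  Also reports the risk-weighted mean
    and the {10, 25, 50, 75, 90} risk-weighted percentiles per axis, plus
    the scalar comparison of Fig-8 type: mean OVF over voxels where
    circuits were detected versus the geometry-wide mean OVF.
    """
    if ovf.shape != risk.local_risk.shape:
        raise ValueError("OVF map and risk map are on different grids")
    if lcf is not None and lcf.shape != ovf.shape:
        raise ValueError("LCF map and OVF map are on different grids")

    occ = np.isfinite(ovf)
    o = ovf[occ]
    w = risk.local_risk[occ]
    edges_o = np.arange(0.0, 1.0 + bin_width, bin_width)
    qs = (10, 25, 50, 75, 90)

    detected = occ & (risk.per_voxel_counts > 0)
    substrate_mean = float(np.nanmean(ovf[detected])) if detected.any() else float("nan")
    geometry_mean = float(np.nanmean(o))

    if lcf is None:
        counts, _ = np.histogram(o, bins=edges_o)
        weighted, _ = np.histogram(o, bins=edges_o, weights=w)
        wmean = (
            float((o * w).sum() / w.sum()) if w.sum() > 0 else float("nan"),
            None,
        )
        pct = {"ovf": _weighted_percentiles(o, w, qs)} if w.sum() > 0 else {}
        return RiskWeightedDistribution(
            edges_o, None, counts, weighted, wmean, pct, substrate_mean, geometry_mean
        )

    both = occ & np.isfinite(lcf)
    o2, l2, w2 = ovf[both], lcf[both], risk.local_risk[both]
    edges_l = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _, _ = np.histogram2d(o2, l2, bins=[edges_o, edges_l])
    weighted, _, _ = np.histogram2d(o2, l2, bins=[edges_o, edges_l], weights=w2)
    if w2.sum() > 0:
        wmean = (
            float((o2 * w2).sum() / w2.sum()),
            float((l2 * w2).sum() / w2.sum()),
        )
        pct = {
            "ovf": _weighted_percentiles(o2, w2, qs),
            "lcf": _weighted_percentiles(l2, w2, qs),
        }
    else:
        wmean, pct = (float("nan"), float("nan")), {}
    return RiskWeightedDistribution(
        edges_o, edges_l, counts, weighted, wmean, pct, substrate_mean, geometry_mean
    )
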