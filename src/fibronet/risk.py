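"""Global and local micro-reentry risk over network ensembles.

One network realisation is a single draw of the transverse-edge
randomness.  The *global risk* lambda of a realisation is the per-beat
probability that a uniformly random conduction-block event induces
reentry:

    lambda = N / (number of block opportunities),

with N the number of reentry-inducing (node, direction) pairs — directly
proportional to the substrate count, and in [0, 1].  The *local risk* of
voxel v apportions lambda by that voxel's share of identified circuits:

    R_v = lambda * N_v / sum_v N_v,

so that the local risks sum back to lambda exactly.  Because single
realisations identify circuits sparsely, risk maps pool a fixed number of
sampled circuits across an ensemble of independently drawn networks;
Gaussian smoothing (sigma = 5 voxels by default) is applied only when
rendering maps, never before computing lambda or cluster statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .geometry import OrientationField, VoxelGeometry
from .network import CouplingConfig, FibreCoupler, NullCoupler
from .substrate import DDMConfig, SubstrateResult, find_substrate
from .tractography import TractographyParams, TractSet, generate_tract_set


@dataclass
class RiskMap:
    lambda_: float  # global risk: reentry-initiation rate per paced beat
    per_voxel_counts: np.ndarray  # pooled circuit counts N_v
    local_risk: np.ndarray  # R_v, sums to lambda_
    ensemble_size: int
    sigma: float = 5.0  # smoothing width for map rendering, voxels
    mean_substrates: float = 0.0  # ensemble-mean inducing (node, direction) pairs
    lambdas: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    member_voxels: list = dc_field(default_factory=list)  # per-member detected voxels
    provenance: dict = dc_field(default_factory=dict)

    @property
    def lambda_se(self) -> float:
        """Standard error of the ensemble-mean global risk."""
        if len(self.lambdas) < 2:
            return float("nan")
        return float(self.lambdas.std(ddof=1) / np.sqrt(len(self.lambdas)))

    def smoothed(self) -> np.ndarray:
        return smooth_map(self.local_risk, self.sigma)


def estimate_global_risk(result: SubstrateResult, net=None) -> float:
    """Per-beat reentry-induction rate under uniform block susceptibility."""
    if result.n_opportunities == 0:
        raise ValueError("network has no edges: no block opportunities")
    return result.n_substrates / result.n_opportunities


def local_risk(counts: np.ndarray, lambda_: float) -> np.ndarray:
    """Apportion the global risk to voxels by circuit share (R_v).

    R_v = lambda * N_v / sum(N_v); the sum over voxels returns lambda.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        if lambda_ > 0:
            raise ValueError("lambda > 0 with all-zero circuit counts")
        return np.zeros_like(counts)
    return lambda_ * counts / total


def smooth_map(values: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic 3-d Gaussian smoothing that preserves the map total.

    The kernel is truncated at 4 sigma; reflective boundaries keep the
    total mass inside the grid (mass that would leave is mirrored back),
    so constant maps are unchanged and the sum is conserved.  A final
    renormalization removes residual floating-point drift; ``sigma = 0``
    is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    values = np.asarray(values, dtype=float)
    if sigma == 0:
        return values.copy()
    out = ndimage.gaussian_filter(values, sigma=sigma, mode="reflect", truncate=4.0)
    total_in, total_out = values.sum(), out.sum()
    if total_out > 0:
        out *= total_in / total_out
    return out


def ensemble_risk(
    geom: VoxelGeometry,
    field: OrientationField | None,
    builder: str,
    coupling: CouplingConfig,
    ddm_cfg: DDMConfig,
    n_networks: int = 50,
    n_circuits_sampled: int = 1000,
    rng: np.random.Generator | None = None,
    tracts: TractSet | None = None,
    tract_params: TractographyParams | None = None,
    regenerate_tracts: bool = False,
    regenerate_nodes: bool = False,
    sigma: float = 5.0,
) -> RiskMap:
    """Pool substrate detections over an ensemble of random networks.

    Each member redraws the transverse-edge randomness; the tract set
    (fibre model) and node placement (null model) are generated once and
    held fixed unless ``regenerate_tracts`` / ``regenerate_nodes`` is
    set.  Per-member global risks are averaged and a fixed number of
    identified circuits is sampled per member (uniformly, with
    replacement) to accumulate the per-voxel counts.  Fully seeded and
    deterministic for a fixed ``rng``.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if builder not in ("fibre", "null"):
        raise ValueError(f"unknown builder {builder!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    d_sep = (tract_params or TractographyParams()).d_sep

    coupler = None
    if builder == "fibre":
        if field is None:
            raise ValueError("fibre model needs an orientation field")
        if tracts is None:
            tracts = generate_tract_set(
                geom, field, tract_params or TractographyParams(), rng
            )
        coupler = FibreCoupler(tracts, coupling.cutoff)
    else:
        coupler = NullCoupler(geom, d_sep, coupling.cutoff, rng)

    counts = np.zeros(geom.shape, dtype=np.int64)
    lambdas = np.empty(n_networks)
    n_substrates = np.empty(n_networks)
    member_voxels: list = []
    for m in range(n_networks):
        member_seed = int(rng.integers(2**31 - 1))
        cfg_m = CouplingConfig(
            c=coupling.c, r=coupling.r, cutoff=coupling.cutoff, seed=member_seed
        )
        if builder == "fibre":
            if regenerate_tracts and m > 0:
                tracts = generate_tract_set(
                    geom, field, tract_params or TractographyParams(), rng
                )
                coupler = FibreCoupler(tracts, coupling.cutoff)
            net = coupler.network(cfg_m)
        else:
            if regenerate_nodes and m > 0:
                coupler = NullCoupler(
                    geom, d_sep, coupling.cutoff, np.random.default_rng(member_seed)
                )
            net = coupler.network(cfg_m)
        result = find_substrate(
            net,
            ddm_cfg,
            grid_shape=geom.shape,
            circuits=n_circuits_sampled if n_circuits_sampled else "none",
            rng=rng,
        )
        lambdas[m] = (
            estimate_global_risk(result) if result.n_opportunities else 0.0
        )
        n_substrates[m] = result.n_substrates
        counts += result.per_voxel_counts
        member_voxels.append(np.argwhere(result.per_voxel_counts > 0))

    lam = float(lambdas.mean())
    return RiskMap(
        lambda_=lam,
        per_voxel_counts=counts,
        local_risk=local_risk(counts, lam),
        ensemble_size=n_networks,
        sigma=sigma,
        mean_substrates=float(n_substrates.mean()),
        member_voxels=member_voxels,
        lambdas=lambdas,
        provenance={
            "builder": builder,
            "coupling": coupling,
            "ddm": ddm_cfg,
            "n_circuits_sampled": n_circuits_sampled,
        },
    )
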