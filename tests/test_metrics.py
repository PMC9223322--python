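import numpy as np
import pytest

from fibronet import (
    MetricsConfig,
    RiskMap,
    build_null_network,
    CouplingConfig,
    longitudinal_connection_fraction,
    occupied_voxel_fraction,
    risk_weighted_distribution,
    substrate_cluster_count,
)
from fibronet.geometry import VoxelGeometry
from fibronet.metrics import cluster_count, ensemble_cluster_count, node_lcf, sphere_offsets
from fibronet.network import LONGITUDINAL, TRANSVERSE, SpatialNetwork


def lattice_sphere_size(r):
    """Brute-force oracle: lattice points with centre distance <= r."""
    n = 0
    R = int(np.ceil(r))
    for dx in range(-R, R + 1):
        for dy in range(-R, R + 1):
            for dz in range(-R, R + 1):
                if dx * dx + dy * dy + dz * dz <= r * r:
                    n += 1
    return n


class TestOVF:
    def test_deep_interior_voxel_reads_one(self):
        geom = VoxelGeometry(np.ones((15, 15, 15), bool))
        ovf = occupied_voxel_fraction(geom, 5.0)
        assert ovf[7, 7, 7] == pytest.approx(1.0)

    def test_isolated_voxel_is_one_over_sphere(self):
        mask = np.zeros((13, 13, 13), bool)
        mask[6, 6, 6] = True
        ovf = occupied_voxel_fraction(VoxelGeometry(mask), 5.0)
        assert ovf[6, 6, 6] == pytest.approx(1.0 / lattice_sphere_size(5.0))
        assert len(sphere_offsets(5.0)) == lattice_sphere_size(5.0)

    def test_slab_surface_voxel_reads_half(self):
        mask = np.zeros((24, 24, 24), bool)
        mask[:, :, :12] = True
        ovf = occupied_voxel_fraction(VoxelGeometry(mask), 5.0)
        assert ovf[12, 12, 11] == pytest.approx(0.5, abs=0.08)

    def test_values_in_unit_interval_and_nan_outside(self, slab):
        geom, _ = slab
        ovf = occupied_voxel_fraction(geom, 5.0)
        vals = ovf[geom.mask]
        assert np.all((vals > 0) & (vals <= 1))
        assert np.isnan(ovf[~geom.mask]).all()

    def test_translation_invariance(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[4:9, 4:9, 4:9] = True
        a = occupied_voxel_fraction(VoxelGeometry(mask), 3.0)
        shifted = np.roll(mask, (5, 5, 5), axis=(0, 1, 2))
        b = occupied_voxel_fraction(VoxelGeometry(shifted), 3.0)
        np.testing.assert_allclose(a[4:9, 4:9, 4:9], b[9:14, 9:14, 9:14])

    def test_monotone_under_adding_tissue(self, rng):
        mask = rng.random((12, 12, 12)) < 0.3
        mask[6, 6, 6] = True
        a = occupied_voxel_fraction(VoxelGeometry(mask), 4.0)
        mask2 = mask.copy()
        empt = np.argwhere(~mask2)
        add = empt[rng.integers(len(empt))]
        mask2[tuple(add)] = True
        b = occupied_voxel_fraction(VoxelGeometry(mask2), 4.0)
        common = mask & mask2
        assert np.all(b[common] >= a[common] - 1e-12)

    def test_invalid_radius(self, slab):
        with pytest.raises(ValueError):
            occupied_voxel_fraction(slab[0], 0.0)


def _toy_net(edges, kinds, n=6):
    pos = np.stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)], axis=1)
    return SpatialNetwork(
        positions=pos,
        voxels=np.floor(pos).astype(np.int64),
        tract_ids=np.zeros(n, np.int64),
        edges=np.array(edges, np.int64),
        kinds=np.array(kinds, np.uint8),
    )


class TestLCF:
    def test_pure_chain_reads_one(self):
        net = _toy_net(
            [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5]], [LONGITUDINAL] * 5
        )
        lcf = longitudinal_connection_fraction(net)
        assert np.nanmin(lcf) == pytest.approx(1.0)

    def test_mixed_node_fraction(self):
        # node 1: two longitudinal + two transverse -> 0.5
        net = _toy_net(
            [[0, 1], [1, 2], [1, 3], [1, 4]],
            [LONGITUDINAL, LONGITUDINAL, TRANSVERSE, TRANSVERSE],
        )
        assert node_lcf(net)[1] == pytest.approx(0.5)

    def test_null_network_is_an_error(self, slab):
        geom, _ = slab
        net = build_null_network(
            geom, CouplingConfig(c=1.0, seed=0), rng=np.random.default_rng(0)
        )
        with pytest.raises(ValueError, match="not defined for the fibre-less"):
            longitudinal_connection_fraction(net)

    def test_removing_transverse_edges_never_decreases_lcf(self, rng):
        # the documented mechanism: LCF can rise purely because transverse
        # coupling is removed, with no new longitudinal connections
        edges = [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [0, 2], [1, 3], [2, 4], [3, 5], [0, 5]]
        kinds = [LONGITUDINAL] * 5 + [TRANSVERSE] * 5
        net = _toy_net(edges, kinds)
        before = node_lcf(net)
        keep = rng.random(10) < 0.5
        keep[:5] = True  # longitudinal edges are permanent
        net2 = _toy_net(
            [e for e, k in zip(edges, keep) if k],
            [k_ for k_, k in zip(kinds, keep) if k],
        )
        after = node_lcf(net2)
        ok = ~np.isnan(before) & ~np.isnan(after)
        assert np.all(after[ok] >= before[ok] - 1e-12)


class TestClusterCount:
    def test_coincident_sample_is_one_cluster(self, rng):
        voxels = np.tile([[5.0, 5.0, 5.0]], (1000, 1))
        cc = substrate_cluster_count(voxels, MetricsConfig(n_bootstrap=5), rng)
        assert cc.n_clusters == 1

    def test_fully_dispersed_sample_counts_every_point(self, rng):
        # 1000 lattice points with spacing 15 > eps = 10
        grid = np.stack(
            np.meshgrid(
                np.arange(10) * 15.0, np.arange(10) * 15.0, np.arange(10) * 15.0,
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        cc = substrate_cluster_count(grid, MetricsConfig(n_bootstrap=5), rng)
        assert cc.n_clusters == 1000

    def test_two_groups_well_separated(self, rng):
        a = rng.normal(scale=1.0, size=(500, 3))
        b = rng.normal(scale=1.0, size=(500, 3)) + [50.0, 0, 0]  # 5 eps apart
        cc = substrate_cluster_count(np.vstack([a, b]), MetricsConfig(n_bootstrap=5), rng)
        assert cc.n_clusters == 2

    def test_count_non_increasing_in_eps(self, rng):
        pts = rng.uniform(0, 60, size=(300, 3))
        counts = [cluster_count(pts, eps) for eps in (2.0, 5.0, 10.0, 20.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_substrate_rejected(self, rng):
        with pytest.raises(ValueError):
            substrate_cluster_count(np.empty((0, 3)), MetricsConfig(), rng)

    def test_ensemble_cluster_count_averages_members(self, rng):
        tight = np.tile([[1.0, 1.0, 1.0]], (40, 1))
        spread = np.stack(
            np.meshgrid(np.arange(5) * 20.0, np.arange(5) * 20.0, [0.0], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        cfg = MetricsConfig(n_sampled_voxels=25, n_bootstrap=20)
        cc = ensemble_cluster_count([tight, spread], cfg, rng)
        assert 1 <= cc.bootstrap_mean <= 25
        assert cc.bootstrap_counts[0] == 1
        assert cc.bootstrap_counts[1] == 25


class TestRiskWeightedDistribution:
    def _risk_map(self, counts, lam):
        from fibronet import local_risk

        return RiskMap(
            lambda_=lam,
            per_voxel_counts=counts,
            local_risk=local_risk(counts.astype(float), lam),
            ensemble_size=1,
        )

    def test_uniform_risk_matches_unweighted_shape(self, rng):
        ovf = np.clip(rng.random((6, 6, 2)), 0.01, 0.99)
        counts = np.ones((6, 6, 2), int)
        rm = self._risk_map(counts, 0.5)
        dist = risk_weighted_distribution(rm, ovf)
        np.testing.assert_allclose(
            dist.weighted / dist.weighted.sum(),
            dist.counts / dist.counts.sum(),
            atol=1e-12,
        )

    def test_point_mass_weighted_mean_is_that_voxel(self, rng):
        ovf = np.clip(rng.random((5, 5, 2)), 0.01, 0.99)
        lcf = np.clip(rng.random((5, 5, 2)), 0.01, 0.99)
        counts = np.zeros((5, 5, 2), int)
        counts[2, 3, 1] = 11
        rm = self._risk_map(counts, 0.2)
        dist = risk_weighted_distribution(rm, ovf, lcf)
        assert dist.weighted_mean[0] == pytest.approx(ovf[2, 3, 1])
        assert dist.weighted_mean[1] == pytest.approx(lcf[2, 3, 1])
        assert dist.substrate_mean_ovf == pytest.approx(ovf[2, 3, 1])

    def test_weighted_mean_matches_direct_summation(self, rng):
        # ten-voxel toy summed by hand
        ovf = np.linspace(0.1, 0.9, 10).reshape(10, 1, 1)
        counts = np.arange(10).reshape(10, 1, 1)
        rm = self._risk_map(counts, 0.3)
        dist = risk_weighted_distribution(rm, ovf)
        w = rm.local_risk.ravel()
        expected = (ovf.ravel() * w).sum() / w.sum()
        assert dist.weighted_mean[0] == pytest.approx(expected)
        for q, v in dist.percentiles["ovf"].items():
            assert 0.1 <= v <= 0.9

    def test_grid_mismatch_rejected(self, rng):
        rm = self._risk_map(np.ones((3, 3, 1), int), 0.1)
        with pytest.raises(ValueError, match="different grids"):
            risk_weighted_distribution(rm, np.ones((4, 4, 1)))
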