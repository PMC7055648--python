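"""Multistage clustering: k-means stages, symmetry, spatial constraints."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from mesoconn.errors import (
    DegenerateInputError,
    IllPosedRegressionError,
    InfeasibleClusteringError,
    InvalidSpecError,
)
from mesoconn.netmetrics import zrand_score
from mesoconn.parcellation import (
    ParcellationParams,
    enforce_spatial_constraints,
    functional_kmeans,
    global_signal_regression,
    mirror_assign,
    run_parcellation,
    spatial_kmeans_left,
)

PARAMS = ParcellationParams(k_spatial=2, k_functional=2, n_replicates=3, seed=0)


class TestSpatialKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob_a = rng.normal(0, 1, (50, 3)) + [-100, 0, 0]
        blob_b = rng.normal(0, 1, (50, 3)) + [-10, 500, 0]
        pts = np.vstack([blob_a, blob_b])
        cl = spatial_kmeans_left(pts, PARAMS)
        labels = cl.assignment
        assert len(np.unique(labels[:50])) == 1
        assert len(np.unique(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_points_assigned_to_nearest_centroid(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-100, 0, (200, 3))
        params = ParcellationParams(k_spatial=8, k_functional=2, seed=1)
        cl = spatial_kmeans_left(pts, params)
        nearest = np.argmin(cdist(pts, cl.centroids), axis=1)
        assert np.array_equal(nearest, cl.assignment)

    def test_too_few_points(self):
        with pytest.raises(InfeasibleClusteringError):
            spatial_kmeans_left(np.zeros((1, 3)), PARAMS)


class TestMirrorAssign:
    def _left_clustering(self, seed=0, k=5):
        rng = np.random.default_rng(seed)
        pts = rng.uniform([-150, -300, -80], [0, 300, 80], (300, 3))
        params = ParcellationParams(k_spatial=k, k_functional=2, seed=seed)
        return pts, spatial_kmeans_left(pts, params)

    def test_centroids_exactly_reflected(self):
        pts, left = self._left_clustering()
        right = pts.copy()
        right[:, 0] *= -1
        both = mirror_assign(left, right)
        assert np.array_equal(
            both.centroids[left.k :, 0], -both.centroids[: left.k, 0]
        )
        assert np.array_equal(both.centroids[left.k :, 1:], both.centroids[: left.k, 1:])

    def test_mirrored_population_gives_identical_cluster_sizes(self):
        pts, left = self._left_clustering(seed=2)
        right = pts.copy()
        right[:, 0] *= -1
        both = mirror_assign(left, right)
        l_sizes = np.bincount(both.assignment[: len(pts)], minlength=left.k)
        r_sizes = np.bincount(both.assignment[len(pts) :] - left.k, minlength=left.k)
        assert np.array_equal(l_sizes, r_sizes)

    def test_nearest_centroid_matches_bruteforce(self):
        pts, left = self._left_clustering(seed=3)
        rng = np.random.default_rng(4)
        right = rng.uniform([0, -300, -80], [150, 300, 80], (100, 3))
        both = mirror_assign(left, right)
        brute = np.argmin(cdist(right, both.centroids[left.k :]), axis=1) + left.k
        assert np.array_equal(both.assignment[len(pts) :], brute)

    def test_cell_on_mirrored_centroid(self):
        pts, left = self._left_clustering(seed=5)
        target = left.centroids[2].copy()
        target[0] *= -1
        both = mirror_assign(left, target[None, :])
        assert both.assignment[-1] == 2 + left.k

    def test_empty_right_rejected(self):
        _, left = self._left_clustering()
        with pytest.raises(DegenerateInputError):
            mirror_assign(left, np.empty((0, 3)))

    def test_homotopic_map_is_bijection(self):
        pts, left = self._left_clustering(seed=6)
        both = mirror_assign(left, pts * [-1, 1, 1])
        hmap = both.homotopic_map()
        assert np.array_equal(hmap[hmap], np.arange(2 * left.k))
        assert np.all(hmap != np.arange(2 * left.k))


class TestGlobalSignalRegression:
    def test_residual_orthogonal_to_global(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(0, 1, (30, 200)) + rng.normal(0, 1, 200)
        resid = global_signal_regression(traces)
        g = traces.mean(axis=0)
        gc = g - g.mean()
        assert np.all(np.abs(resid @ gc) < 1e-8 * np.linalg.norm(gc) * 200)

    def test_idempotent_because_residual_global_mean_vanishes(self):
        rng = np.random.default_rng(1)
        traces = rng.normal(0, 1, (20, 150)) + 3 * rng.normal(0, 1, 150)
        once = global_signal_regression(traces)
        # the residual global signal is identically ~0 (regression removes
        # it exactly), so a second pass could only be the identity
        assert np.allclose(once.mean(axis=0), 0.0, atol=1e-10)

    def test_trace_equal_to_global_gives_zero_residual(self):
        g = np.sin(np.linspace(0, 10, 100))
        traces = np.tile(g, (5, 1))
        resid = global_signal_regression(traces)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_constant_global_rejected(self):
        with pytest.raises(IllPosedRegressionError):
            global_signal_regression(np.vstack([np.ones(50), -np.ones(50)]))


class TestFunctionalKmeans:
    def test_block_diagonal_recovered(self):
        rng = np.random.default_rng(0)
        labels_true = np.repeat(np.arange(3), 10)
        c = np.where(labels_true[:, None] == labels_true[None, :], 0.9, 0.05)
        c += rng.normal(0, 0.01, c.shape)
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 1.0)
        params = ParcellationParams(k_spatial=30, k_functional=3, seed=0)
        labels = functional_kmeans(c, params)
        for m in range(3):
            assert len(np.unique(labels[labels_true == m])) == 1
        assert len(np.unique(labels)) == 3

    def test_duplicate_rows_share_label(self):
        rng = np.random.default_rng(1)
        c = rng.normal(0, 1, (10, 10))
        c[7] = c[3]
        params = ParcellationParams(k_spatial=10, k_functional=4, seed=1)
        labels = functional_kmeans(c, params)
        assert labels[7] == labels[3]

    def test_affine_invariance_of_rows(self):
        rng = np.random.default_rng(2)
        c = rng.normal(0, 1, (12, 12))
        params = ParcellationParams(k_spatial=12, k_functional=3, seed=2)
        a = functional_kmeans(c, params)
        b = functional_kmeans(2.5 * c + 7.0, params)
        # same partition up to relabeling
        assert zrand_score(a, b).w_xy == zrand_score(a, a).w_xy

    def test_k_too_large(self):
        with pytest.raises(InfeasibleClusteringError):
            functional_kmeans(np.eye(3), ParcellationParams(k_functional=5, seed=0))


class TestEnforceSpatialConstraints:
    def test_compact_cluster_unchanged(self):
        rng = np.random.default_rng(0)
        cents = rng.uniform(-25, 0, (6, 3))  # diameter well under 200
        labels = np.zeros(6, dtype=np.intp)
        params = ParcellationParams(k_spatial=6, k_functional=1, seed=0)
        parc = enforce_spatial_constraints(labels, cents, params)
        assert parc.n_parcels == 2  # one left + its right mirror

    def test_distant_groups_split(self):
        cents = np.vstack([np.zeros((3, 3)), np.full((3, 3), [-300, 0, 0])])
        cents[:3] += np.random.default_rng(1).normal(0, 5, (3, 3))
        cents[3:] += np.random.default_rng(2).normal(0, 5, (3, 3))
        labels = np.zeros(6, dtype=np.intp)
        params = ParcellationParams(k_spatial=6, k_functional=1, seed=0)
        parc = enforce_spatial_constraints(labels, cents, params)
        assert parc.n_parcels == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_constraints_hold_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        cents = rng.uniform([-700, -700, -200], [0, 700, 200], (60, 3))
        labels = rng.integers(0, 5, 60).astype(np.intp)
        params = ParcellationParams(k_spatial=60, k_functional=5, seed=seed)
        parc = enforce_spatial_constraints(labels, cents, params)
        assert np.all(parc.diameters() < params.max_diameter)
        # gap between linkage-separated parcels of one functional cluster
        for _, _, gap in parc.within_functional_gaps():
            assert gap >= params.min_gap
        partner = parc.homotopic_partner
        assert np.array_equal(partner[partner], np.arange(parc.n_parcels))
        assert np.all(partner != np.arange(parc.n_parcels))

    def test_diameter_enforced_even_when_gap_unsatisfiable(self):
        # a 500 px chain of near-touching points must be split by diameter
        cents = np.column_stack(
            [np.linspace(-500, -10, 25), np.zeros(25), np.zeros(25)]
        )
        labels = np.zeros(25, dtype=np.intp)
        params = ParcellationParams(k_spatial=25, k_functional=1, seed=0)
        parc = enforce_spatial_constraints(labels, cents, params)
        assert np.all(parc.diameters() < params.max_diameter)
        assert parc.n_parcels >= 6  # at least 3 chunks per hemisphere


class TestRunParcellation:
    @pytest.fixture(scope="class")
    @staticmethod
    def parcellated(tiny_study):
        params = ParcellationParams(
            k_spatial=40, k_functional=8, n_replicates=4, seed=7
        )
        return run_parcellation(tiny_study, params), params

    def test_every_parcel_has_distinct_partner(self, parcellated):
        parc, _ = parcellated
        partner = parc.homotopic_partner
        assert np.array_equal(partner[partner], np.arange(parc.n_parcels))
        assert np.all(partner != np.arange(parc.n_parcels))
        assert np.all(parc.hemisphere_of_parcel[partner] != parc.hemisphere_of_parcel)

    def test_determinism(self, tiny_study, parcellated):
        parc, params = parcellated
        again = run_parcellation(tiny_study, params)
        for s in parc.parcel_of_cell:
            assert np.array_equal(parc.parcel_of_cell[s], again.parcel_of_cell[s])
        assert np.array_equal(parc.parcel_centroids, again.parcel_centroids)

    def test_stats_reported(self, parcellated):
        parc, _ = parcellated
        assert parc.stats["n_parcels"] == parc.n_parcels
        assert 0.0 <= parc.stats["fraction_all_subjects"] <= 1.0

    def test_parcels_recover_planted_fine_modules(self, tiny_study, parcellated):
        # parcel boundaries should align with the spatially compact planted
        # fine modules: z-Rand of cell-level labels significantly > 0
        parc, _ = parcellated
        subject = tiny_study.subjects[0]
        cell_parcel = parc.parcel_of_cell[subject]
        truth = tiny_study.structure.fine_of_cell
        res = zrand_score(cell_parcel, truth)
        assert res.z > 2.0
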