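"""Hub metrics, z-Rand, geometry profiles, Mantel, similarity reports."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from mesoconn.community import Hierarchy, Partition
from mesoconn.connectivity import FCNetwork
from mesoconn.errors import (
    IncompatibleNetworksError,
    InvalidSpecError,
    UndefinedCorrelationError,
    UndefinedVarianceError,
)
from mesoconn.multilayer import FlexibilityProfile
from mesoconn.netmetrics import (
    absolute_strength,
    distance_profile,
    flexibility_participation_correlation,
    hemisphere_similarity,
    hierarchy_participation,
    mantel_test,
    participation_coefficient,
    similarity_report,
    zrand_score,
)


def _net(w, coords=None, **kw):
    w = np.asarray(w, dtype=float)
    if coords is None:
        coords = np.zeros((w.shape[0], 3))
    return FCNetwork(weights=w, coords=coords, **kw)


class TestParticipation:
    def test_all_connections_in_own_module(self):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.3
        labels = np.array([0, 0, 0, 1, 1, 1])
        p = participation_coefficient(w, labels)
        assert p[0] == 0.0

    def test_equal_four_way_split_exact(self):
        # node 0 connects with equal weight to one node in each of 4 modules
        w = np.zeros((9, 9))
        for j in (1, 3, 5, 7):
            w[0, j] = w[j, 0] = 0.25
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3])
        p = participation_coefficient(w, labels)
        assert abs(p[0] - 0.75) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(0, 1, (20, 20))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        labels = rng.integers(0, 4, 20)
        p = participation_coefficient(w, labels)
        pos = np.clip(w, 0, None)
        for i in range(20):
            k = pos[i].sum()
            if k == 0:
                assert p[i] == 0.0
                continue
            s = sum(
                (pos[i, labels == c].sum() / k) ** 2 for c in np.unique(labels)
            )
            assert abs(p[i] - (1 - s)) < 1e-12

    def test_zero_positive_strength_convention(self):
        w = -np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        p = participation_coefficient(w, np.array([0, 0, 1, 1]))
        assert np.all(p == 0.0)

    def test_bounded_by_module_count(self):
        rng = np.random.default_rng(9)
        w = np.abs(rng.normal(0, 1, (30, 30)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        labels = rng.integers(0, 5, 30)
        n_c = len(np.unique(labels))
        p = participation_coefficient(w, labels)
        assert np.all(p <= 1 - 1 / n_c + 1e-12)


class TestStrength:
    def test_closed_forms_and_bruteforce(self):
        assert np.all(absolute_strength(np.zeros((5, 5))) == 0.0)
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = -0.5
        assert absolute_strength(w)[0] == 1.0
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (12, 12))
        np.fill_diagonal(m, 0.0)
        s = absolute_strength(m)
        for i in range(12):
            assert abs(s[i] - sum(abs(m[i, j]) for j in range(12) if j != i)) < 1e-12


class TestHierarchyParticipation:
    def test_single_level_mean_equals_level(self):
        rng = np.random.default_rng(1)
        w = np.abs(rng.normal(0, 1, (12, 12)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        part = Partition(labels=rng.integers(0, 3, 12))
        hier = Hierarchy(levels=[part])
        hm = hierarchy_participation(_net(w), hier)
        assert np.allclose(hm.participation_mean, hm.participation_per_level[:, 0])

    def test_identical_levels_perfectly_correlated(self):
        rng = np.random.default_rng(2)
        w = np.abs(rng.normal(0, 1, (15, 15)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        part = Partition(labels=rng.integers(0, 4, 15))
        hm = hierarchy_participation(_net(w), Hierarchy(levels=[part, part]))
        assert abs(hm.cross_level_corr[0, 1] - 1.0) < 1e-12

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_connectors_rank_highest(self, seed):
        # 4 modules; designated connector nodes spread positive weight evenly
        rng = np.random.default_rng(seed)
        n = 40
        labels = np.repeat(np.arange(4), 10)
        w = np.where(labels[:, None] == labels[None, :], 0.6, 0.02)
        connectors = [0, 10, 20, 30]
        for c in connectors:
            w[c, :] = 0.3
            w[:, c] = 0.3
        w = w + rng.normal(0, 0.01, (n, n))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        hm = hierarchy_participation(
            _net(w), Hierarchy(levels=[Partition(labels=labels)])
        )
        top4 = set(np.argsort(hm.participation_mean)[-4:])
        assert top4 == set(connectors)


class TestZRand:
    def test_hand_counted_components(self):
        labels = np.repeat([0, 1], 4)  # 2 balanced modules on 8 nodes
        res = zrand_score(labels, labels)
        assert res.w_xy == 12 and res.w_x == 12 and res.w_y == 12
        assert res.w_total == 28
        assert res.z > 0

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 30)
        y = rng.integers(0, 4, 30)
        a = zrand_score(x, y)
        b = zrand_score(y, x)
        assert abs(a.z - b.z) < 1e-12
        perm = np.array([1, 2, 0])
        c = zrand_score(perm[x], y)
        assert abs(a.z - c.z) < 1e-12

    def test_null_calibration_monte_carlo(self):
        rng = np.random.default_rng(1)
        zs = []
        for _ in range(1000):
            x = rng.integers(0, 4, 50)
            y = rng.integers(0, 4, 50)
            zs.append(zrand_score(x, y).z)
        assert abs(np.mean(zs)) < 0.1

    def test_degenerate_partitions_rejected(self):
        with pytest.raises(UndefinedVarianceError):
            zrand_score(np.zeros(6, dtype=int), np.arange(6))


class TestDistanceProfile:
    def _geom_net(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        coords = rng.uniform([-200, -400, -100], [200, 400, 100], (n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        w = np.exp(-0.005 * d)
        np.fill_diagonal(w, 0.0)
        return _net(w, coords=coords), d

    def test_uniform_network_single_class(self):
        coords = np.random.default_rng(0).uniform(-100, 100, (20, 3))
        w = np.full((20, 20), 0.3)
        np.fill_diagonal(w, 0.0)
        prof = distance_profile(_net(w, coords), np.linspace(0, 400, 5))
        filled = ~np.isnan(prof.class_proportions[:, 0])
        assert np.all(prof.class_proportions[filled, 1] == 1.0)  # all weak positive

    def test_proportions_sum_to_one(self):
        net, _ = self._geom_net(1)
        prof = distance_profile(net, np.linspace(0, 900, 10))
        filled = ~np.isnan(prof.class_proportions).any(axis=1)
        assert np.allclose(prof.class_proportions[filled].sum(axis=1), 1.0, atol=1e-12)

    def test_exponential_decay_slope_recovered(self):
        net, d = self._geom_net(2, n=80)
        edges = np.linspace(0, 600, 13)
        prof = distance_profile(net, edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        # pool within- and between-hemisphere means weighted equally
        mean_w = np.nanmean(
            np.vstack([prof.mean_weight_within, prof.mean_weight_between]), axis=0
        )
        ok = ~np.isnan(mean_w) & (mean_w > 0)
        slope = np.polyfit(mids[ok], np.log(mean_w[ok]), 1)[0]
        assert abs(slope + 0.005) / 0.005 < 0.2

    def test_empty_bin_is_nan_not_zero(self):
        net, _ = self._geom_net(3)
        prof = distance_profile(net, np.array([0.0, 1.0, 900.0]))
        assert np.all(np.isnan(prof.class_proportions[0]))

    def test_bad_thresholds(self):
        net, _ = self._geom_net(4)
        with pytest.raises(InvalidSpecError):
            distance_profile(net, np.linspace(0, 900, 4), class_thresholds=(0.5, 0.1))


class TestHemisphereSimilarity:
    def _parcellation(self, n_side):
        from mesoconn.parcellation import Parcellation

        n = 2 * n_side
        return Parcellation(
            parcel_of_cell={},
            parcel_centroids=np.zeros((n, 3)),
            homotopic_partner=np.concatenate(
                [np.arange(n_side) + n_side, np.arange(n_side)]
            ),
            n_parcels=n,
            functional_of_parcel=np.zeros(n, dtype=np.intp),
            members=[np.array([i]) for i in range(n)],
            spatial_centroids=np.zeros((n, 3)),
            hemisphere_of_parcel=np.array(["L"] * n_side + ["R"] * n_side),
        )

    def test_mirror_symmetric_network_r_one(self):
        rng = np.random.default_rng(0)
        n_side = 8
        block = rng.normal(0, 1, (n_side, n_side))
        block = 0.5 * (block + block.T)
        np.fill_diagonal(block, 0.0)
        w = np.zeros((2 * n_side, 2 * n_side))
        w[:n_side, :n_side] = block
        w[n_side:, n_side:] = block
        r = hemisphere_similarity(_net(w), self._parcellation(n_side))
        assert abs(r - 1.0) < 1e-12

    def test_independent_hemispheres_mean_near_zero(self):
        rng = np.random.default_rng(1)
        n_side = 10
        rs = []
        for _ in range(100):
            w = np.zeros((2 * n_side, 2 * n_side))
            for sl in (slice(0, n_side), slice(n_side, 2 * n_side)):
                b = rng.normal(0, 1, (n_side, n_side))
                b = 0.5 * (b + b.T)
                np.fill_diagonal(b, 0.0)
                w[sl, sl] = b
            rs.append(hemisphere_similarity(_net(w), self._parcellation(n_side)))
        assert abs(np.mean(rs)) < 0.05


class TestMantel:
    def _sym(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, n))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0.0)
        return a

    def test_self_comparison_floor(self):
        a = self._sym(15, 0)
        r, p = mantel_test(a, a, n_perm=999, seed=1)
        assert r == 1.0
        assert p == pytest.approx(0.001)

    def test_statistic_symmetric_in_argument_order(self):
        a, b = self._sym(12, 1), self._sym(12, 2)
        r1, _ = mantel_test(a, b, n_perm=9, seed=0)
        r2, _ = mantel_test(b, a, n_perm=9, seed=0)
        assert abs(r1 - r2) < 1e-12

    def test_null_calibration(self):
        # under independence P(p <= alpha) <= alpha + 1/(1+n_perm) + MC error
        rng = np.random.default_rng(3)
        hits = 0
        reps = 100
        for k in range(reps):
            a, b = self._sym(12, 100 + 2 * k), self._sym(12, 101 + 2 * k)
            _, p = mantel_test(a, b, n_perm=99, seed=k)
            hits += p <= 0.05
        assert hits / reps <= 0.13

    def test_invalid_args(self):
        a = self._sym(5, 0)
        with pytest.raises(InvalidSpecError):
            mantel_test(a, a, n_perm=0)
        with pytest.raises(IncompatibleNetworksError):
            mantel_test(a, self._sym(6, 1))


class TestSimilarityReport:
    def test_identical_networks_r_one(self):
        w = self_w = np.random.default_rng(0).normal(0, 1, (8, 8))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        nets = [_net(w, subject_id=f"s{i}", condition="spontaneous") for i in range(3)]
        rep = similarity_report(nets)
        assert np.allclose(rep.pairwise_r, 1.0)

    def test_self_vs_other_grouping(self):
        rng = np.random.default_rng(1)
        base = {s: rng.normal(0, 1, (6, 6)) for s in "ab"}
        nets = []
        for s in "ab":
            for cond in ("spontaneous", "PT"):
                w = base[s] + 0.1 * rng.normal(0, 1, (6, 6))
                w = 0.5 * (w + w.T)
                np.fill_diagonal(w, 0.0)
                nets.append(_net(w, subject_id=s, condition=cond))
        rep = similarity_report(nets)
        assert rep.self_similarity > rep.intersubject_similarity

    def test_shape_mismatch(self):
        with pytest.raises(IncompatibleNetworksError):
            similarity_report(
                [_net(np.zeros((3, 3))), _net(np.zeros((4, 4)))]
            )


class TestFlexibilityParticipation:
    def test_identical_vectors_r_one(self):
        v = np.linspace(0, 1, 20)
        prof = FlexibilityProfile(f=v.copy())
        assert abs(flexibility_participation_correlation(prof, v) - 1.0) < 1e-12

    def test_independent_vectors_small_mean(self):
        rng = np.random.default_rng(2)
        rs = [
            flexibility_participation_correlation(
                rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
            )
            for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            flexibility_participation_correlation(np.ones(5), np.arange(5.0))
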