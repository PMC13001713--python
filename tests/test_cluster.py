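"""Cluster-based permutation inference: adjacency, F maps, clustering, p values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speechtrace import cluster
from speechtrace.cluster import (adjacency_from_positions, find_clusters,
                                 permutation_test, pointwise_F_dep,
                                 pointwise_F_indep)


class TestAdjacency:
    def test_triangle_every_pair_adjacent(self):
        adj = adjacency_from_positions(
            np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]))
        assert adj.sum() == 6 and not adj.diagonal().any()

    def test_square_grid_degree_multiset(self, square_positions):
        adj = adjacency_from_positions(square_positions)
        assert sorted(adj.sum(axis=1)) == [2, 2, 3, 3]

    def test_symmetry_on_random_montages(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pos = rng.uniform(-1, 1, size=(12, 2))
            adj = adjacency_from_positions(pos)
            assert np.array_equal(adj, adj.T)
            assert not adj.diagonal().any()

    def test_3d_positions_projected(self):
        from speechtrace.montage import channel_positions

        names, pos = channel_positions()
        adj = adjacency_from_positions(pos)
        assert adj.sum(axis=1).min() >= 2
        # direct scalp neighbors must touch
        assert adj[names.index("Cz"), names.index("C1")]

    def test_duplicate_positions_raise(self):
        with pytest.raises(ValueError):
            adjacency_from_positions(
                np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


class TestPointwiseF:
    def test_indep_equal_means_zero_F(self):
        g1 = np.array([[1.0], [3.0]])
        g2 = np.array([[0.0], [4.0]])
        assert pointwise_F_indep([g1, g2])[0] == pytest.approx(0.0)

    def test_indep_hand_sums_of_squares(self):
        # groups {0,1} and {2,3}: SSB=4, SSW=1, df=(1,2) -> F=8
        F = pointwise_F_indep([np.array([[0.0], [1.0]]),
                               np.array([[2.0], [3.0]])])
        assert F[0] == pytest.approx(8.0)

    def test_indep_null_distribution_calibration(self):
        """Null F values follow F(k-1, N-k)."""
        from scipy import stats

        rng = np.random.default_rng(1)
        k, n = 3, 8
        groups = [rng.normal(size=(n, 10000)) for _ in range(k)]
        F = pointwise_F_indep(groups)
        crit = stats.f.isf(0.05, k - 1, k * n - k)
        assert np.mean(F > crit) == pytest.approx(0.05, abs=0.01)

    def test_dep_identical_conditions_zero_F(self):
        y = np.tile(np.arange(5.0)[:, None, None], (1, 3, 4))
        assert np.allclose(pointwise_F_dep(y), 0.0, atol=1e-12)

    def test_dep_matches_rm_anova_oracle(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(2)
        y = rng.normal(size=(6, 3))
        F = pointwise_F_dep(y.reshape(6, 3, 1))[0]
        df = pd.DataFrame({"y": y.ravel(),
                           "subj": np.repeat(np.arange(6), 3),
                           "cond": np.tile(np.arange(3), 6)})
        oracle = pg.rm_anova(data=df, dv="y", within="cond",
                             subject="subj")["F"].iloc[0]
        assert F == pytest.approx(oracle, rel=1e-9)

    def test_dep_null_pointwise_rejection_rate(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 3, 10000))
        F = pointwise_F_dep(y)
        crit = stats.f.isf(0.05, 2, 18)
        assert np.mean(F > crit) == pytest.approx(0.05, abs=0.01)

    def test_degenerate_indep_raises(self):
        with pytest.raises(ValueError):
            pointwise_F_indep([np.ones((3, 4)), np.full((3, 4), 2.0)])


class TestFindClusters:
    def test_all_zero_map_no_clusters(self):
        adj = np.zeros((4, 4), bool)
        assert find_clusters(np.zeros((4, 10)), 1.0, adj) == []

    def test_constructed_cluster_sum(self):
        """4 mutually adjacent channels x 3 consecutive samples of 10 -> 120."""
        adj = ~np.eye(4, dtype=bool)
        F = np.zeros((4, 9))
        F[:, 3:6] = 10.0
        cl = find_clusters(F, 5.0, adj, min_nb_chan=3)
        assert len(cl) == 1
        assert cl[0].stat == pytest.approx(120.0)
        assert len(cl[0].members) == 12

    def test_isolated_channel_pruned(self):
        adj = np.zeros((3, 3), bool)      # nobody is adjacent
        F = np.zeros((3, 5))
        F[1, 2] = 99.0
        assert find_clusters(F, 5.0, adj, min_nb_chan=3) == []

    def test_min_nb_chan_zero_keeps_isolated_points(self):
        adj = np.zeros((3, 3), bool)
        F = np.zeros((3, 5))
        F[1, 2] = 99.0
        cl = find_clusters(F, 5.0, adj, min_nb_chan=0)
        assert len(cl) == 1 and cl[0].stat == pytest.approx(99.0)

    def test_1d_map_contiguous_runs(self):
        F = np.array([0.0, 6.0, 7.0, 0.0, 8.0, 8.0, 8.0, 0.0])
        cl = find_clusters(F, 5.0, adjacency=None, min_nb_chan=0)
        assert sorted(c.stat for c in cl) == [13.0, 24.0]

    def test_cluster_sums_additive(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(0, 10, size=(6, 20))
        adj = adjacency_from_positions(rng.uniform(-1, 1, (6, 2)))
        for c in find_clusters(F, 5.0, adj, min_nb_chan=0):
            total = sum(F[ch, pt] for ch, pt in c.members)
            assert c.stat == pytest.approx(total)


def brute_force_dependent_p(data, threshold, adjacency, min_nb_chan=0):
    """Independent enumeration oracle for the within-subject permutation null."""
    n_subj, k = data.shape[:2]
    perms = list(itertools.permutations(range(k)))
    obs_clusters = find_clusters(pointwise_F_dep(data), threshold,
                                 adjacency, min_nb_chan)
    obs = obs_clusters[0].stat
    null = []
    for combo in itertools.product(perms, repeat=n_subj):
        y = np.stack([data[s, list(combo[s])] for s in range(n_subj)])
        cl = find_clusters(pointwise_F_dep(y), threshold, adjacency,
                           min_nb_chan)
        null.append(cl[0].stat if cl else 0.0)
    null = np.asarray(null)
    return np.mean(null >= obs - 1e-12)


class TestPermutationTest:
    def test_observed_max_beats_all_permutations(self):
        """A huge effect gets the smallest achievable Monte Carlo p."""
        rng = np.random.default_rng(5)
        data = rng.normal(size=(8, 3, 2, 6))
        data[:, 0] += 50.0                 # overwhelming condition effect
        adj = np.array([[False, True], [True, False]])
        res = permutation_test(data, "dependent", adjacency=adj,
                               n_perm=200, seed=0, min_nb_chan=0)
        assert res.clusters[0].p_value == pytest.approx(1 / 201)

    def test_tiny_instance_matches_exhaustive_enumeration(self):
        """Exact p on a tiny design equals the brute-force enumeration."""
        rng = np.random.default_rng(6)
        data = rng.normal(size=(4, 3, 2, 3))
        data[:, 0] += 1.5
        adj = np.array([[False, True], [True, False]])
        res = permutation_test(data, "dependent", adjacency=adj,
                               exhaustive=True, min_nb_chan=0)
        assert res.clusters, "expected at least one cluster"
        p_oracle = brute_force_dependent_p(data, res.threshold, adj)
        assert res.clusters[0].p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 6 ** 4

    def test_seed_required_for_monte_carlo(self):
        data = np.random.default_rng(7).normal(size=(4, 3, 2, 3))
        with pytest.raises(ValueError):
            permutation_test(data, "dependent",
                             adjacency=np.zeros((2, 2), bool))

    def test_low_permutation_count_warns(self):
        data = np.random.default_rng(8).normal(size=(4, 3, 2, 3))
        with pytest.warns(UserWarning):
            permutation_test(data, "dependent", n_perm=50, seed=1,
                             adjacency=np.zeros((2, 2), bool),
                             min_nb_chan=0)

    def test_affine_invariance_of_p_values(self):
        """F is scale-free, so affine data transforms leave p unchanged."""
        rng = np.random.default_rng(9)
        data = rng.normal(size=(6, 3, 2, 8))
        data[:, 1] += 0.8
        adj = np.array([[False, True], [True, False]])
        r1 = permutation_test(data, "dependent", adjacency=adj, n_perm=300,
                              seed=3, min_nb_chan=0)
        r2 = permutation_test(3.7 * data + 11.0, "dependent", adjacency=adj,
                              n_perm=300, seed=3, min_nb_chan=0)
        assert [c.p_value for c in r1.clusters] == pytest.approx(
            [c.p_value for c in r2.clusters])

    def test_independent_design_detects_group_difference(self):
        rng = np.random.default_rng(10)
        g1 = rng.normal(size=(20, 1, 30))
        g2 = rng.normal(size=(20, 1, 30))
        g2[:, :, 10:20] += 2.0
        g3 = rng.normal(size=(20, 1, 30))
        res = permutation_test([g1, g2, g3], "independent", n_perm=300,
                               seed=4, min_nb_chan=0)
        assert res.significant
        lo, hi = res.significant[0].sample_range()
        assert lo >= 8 and hi <= 22

    def test_exhaustive_rejects_independent_design(self):
        with pytest.raises(ValueError):
            permutation_test([np.zeros((3, 1, 4)), np.ones((3, 1, 4))],
                             "independent", exhaustive=True)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_cluster_member_stats_consistent(seed):
    """Cluster stats always equal the sum of member F values (property)."""
    rng = np.random.default_rng(seed)
    F = rng.uniform(0, 8, size=(5, 12))
    adj = adjacency_from_positions(rng.uniform(-1, 1, (5, 2)))
    for c in find_clusters(F, 4.0, adj, min_nb_chan=1):
        assert c.stat == pytest.approx(F[c.members[:, 0], c.members[:, 1]].sum())
        # members are unique
        assert len({tuple(m) for m in c.members}) == len(c.members)
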