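"""Lineage-space statistics: distances, MI, entropy, autocorrelation,
clusters, and the Mann-Whitney comparison."""

import itertools
import math
import warnings

import numpy as np
import pytest

import microta as m
from microta.analytics import (PairSample, arrested_clusters,
                               cluster_size_distribution, count_zero_crossings,
                               ensemble_autocorrelation, entropy,
                               mann_whitney_lineage, mutual_information,
                               mutual_information_from_counts, sample_pairs,
                               time_since_mrca)
from conftest import four_leaf_tree, six_leaf_arrest_tree, make_node

LAM = m.LAMBDA_DEFAULT


class TestLineageDistance:
    def test_self_distance_zero(self):
        tree = four_leaf_tree()
        assert tree.lineage_distance(3, 3) == 0.0

    def test_all_pairs_by_enumeration(self):
        # MRCA division times: (3,4)->120, (5,6)->180, cross pairs->100
        tree = four_leaf_tree()
        expected = {(3, 4): 130.0, (5, 6): 70.0, (3, 5): 150.0,
                    (3, 6): 150.0, (4, 5): 150.0, (4, 6): 150.0}
        for (i, j), d in expected.items():
            assert tree.lineage_distance(i, j) == d
            assert tree.lineage_distance(j, i) == d  # symmetry

    def test_sisters_definition(self):
        tree = four_leaf_tree()
        assert tree.lineage_distance(3, 4, at_time=250.0) == 130.0

    def test_non_coexisting_cells_rejected(self):
        tree = four_leaf_tree()
        with pytest.raises(ValueError):
            tree.lineage_distance(1, 3)  # cell 1 divided at 120
        with pytest.raises(KeyError):
            tree.lineage_distance(3, 99)

    def test_generic_mrca_helper_matches_tree(self):
        tree = four_leaf_tree()
        parents = {n.id: n.parent for n in tree.nodes}
        births = {n.id: n.birth_time for n in tree.nodes}
        for i, j in itertools.combinations([3, 4, 5, 6], 2):
            assert time_since_mrca(parents, births, i, j, 250.0) == \
                tree.lineage_distance(i, j)


class TestSamplePairs:
    def test_two_cell_tree_pair_is_certain(self):
        nodes = [make_node(0, -1, 0.0, end=60.0, divided=True,
                           children=(1, 2)),
                 make_node(1, 0, 60.0, end=250.0, g=LAM),
                 make_node(2, 0, 60.0, end=250.0, g=0.0)]
        tree = m.LineageTree(nodes, dt=0.5, t_end=250.0, t_onset=100.0)
        for seed in range(5):
            s, = sample_pairs([tree], rng=np.random.default_rng(seed))
            assert s.d == 190.0
            assert s.phi == pytest.approx(LAM)

    def test_one_sample_per_tree(self):
        trees = [four_leaf_tree() for _ in range(10)]
        samples = sample_pairs(trees, rng=np.random.default_rng(1))
        assert len(samples) == 10
        assert all(s.d >= 0 and s.phi >= 0 for s in samples)

    def test_uniform_over_pairs(self):
        lam = LAM
        nodes = [make_node(0, -1, 0.0, end=50.0, divided=True,
                           children=(1, 2)),
                 make_node(1, 0, 50.0, end=250.0, g=lam),
                 make_node(2, 0, 50.0, end=100.0, divided=True,
                           children=(3, 4)),
                 make_node(3, 2, 100.0, end=250.0, g=lam / 2),
                 make_node(4, 2, 100.0, end=250.0, g=0.0)]
        tree = m.LineageTree(nodes, dt=0.5, t_end=250.0, t_onset=100.0)
        rng = np.random.default_rng(2)
        counts = {150.0: 0, 150.0 + 0: 0}
        freq = {}
        for _ in range(900):
            s = sample_pairs([tree], rng=rng)[0]
            key = (round(s.d), round(s.phi, 6))
            freq[key] = freq.get(key, 0) + 1
        # three distinct pairs, each ~1/3
        assert len(freq) == 3
        for v in freq.values():
            assert v == pytest.approx(300, abs=60)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            sample_pairs([], rng=np.random.default_rng(3))


def plugin_mi_oracle(table):
    """Independent direct evaluation of the double-sum MI formula."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            p = table[i, j] / n
            if p == 0:
                continue
            pd_ = table[i, :].sum() / n
            pf_ = table[:, j].sum() / n
            total += p * math.log2(p / (pd_ * pf_))
    return total


class TestMutualInformation:
    def test_perfectly_dependent_binary_is_one_bit(self):
        table = [[2, 0], [0, 2]]
        assert mutual_information_from_counts(table) == pytest.approx(1.0)

    def test_uniform_independent_is_zero(self):
        assert mutual_information_from_counts([[1, 1], [1, 1]]) == 0.0

    def test_hand_evaluated_joint_table(self):
        table = [[4, 0], [1, 3], [1, 3]]
        assert mutual_information_from_counts(table) == pytest.approx(
            plugin_mi_oracle(table), abs=1e-12)
        assert plugin_mi_oracle(table) == pytest.approx(
            0.4591479170272448, abs=1e-12)

    def test_estimator_on_samples_nonnegative_and_bootstrap(self):
        rng = np.random.default_rng(4)
        samples = [PairSample(d=float(d), phi=float(rng.random()))
                   for d in rng.integers(0, 100, size=60)]
        est = mutual_information(samples, rng=rng)
        assert est.mi_bits >= 0
        assert est.sd_bits >= 0
        assert est.n_samples == 60

    def test_deterministic_relation_recovers_marginal_entropy(self):
        # phi an invertible function of d: MI equals H(D) under shared bins
        ds = np.repeat([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0],
                       [5, 3, 8, 2, 4, 6, 1, 3])
        samples = [PairSample(d=d, phi=2.5 * d) for d in ds]
        est = mutual_information(samples, n_bins=8, n_bootstrap=2,
                                 rng=np.random.default_rng(5))
        h_d = entropy(ds, mode="fine", bin_width=10.0)
        assert est.mi_bits == pytest.approx(h_d, abs=1e-9)

    def test_degenerate_binning_warns_and_zeroes(self):
        samples = [PairSample(d=1.0, phi=p) for p in (0.1, 0.2, 0.9)]
        with pytest.warns(UserWarning, match="degenerate"):
            est = mutual_information(samples,
                                     rng=np.random.default_rng(6))
        assert est.mi_bits == 0.0


class TestEntropy:
    def test_half_arrested_is_one_bit(self):
        values = [0.0] * 50 + [LAM] * 50
        assert entropy(values, mode="binary") == pytest.approx(1.0, abs=1e-12)

    def test_identical_values_zero_bits(self):
        assert entropy([0.013] * 40, mode="fine", bin_width=1e-4) == 0.0
        assert entropy([0.013] * 40, mode="binary") == 0.0

    def test_distinct_values_reach_log2_n(self):
        values = np.arange(256) * 1.0
        assert entropy(values, mode="fine", bin_width=0.5) == pytest.approx(
            8.0)

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(7)
        values = rng.random(200)
        h = entropy(values, mode="fine", bin_width=0.1)
        assert entropy(rng.permutation(values), mode="fine",
                       bin_width=0.1) == pytest.approx(h)
        assert 0 <= h <= math.log2(10) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy([], mode="binary")


class TestEnsembleAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(8)
        series = [rng.normal(size=300) for _ in range(5)]
        lags, mean_abs, mean_acf, _ = ensemble_autocorrelation(series, 50)
        assert mean_abs[0] == pytest.approx(1.0)
        assert mean_acf[0] == pytest.approx(1.0)

    def test_sinusoid_is_oscillatory(self):
        t = np.arange(0, 300)
        series = [np.sin(2 * np.pi * t / 60 + ph) for ph in (0.0, 1.0, 2.0)]
        _, _, mean_acf, zeros = ensemble_autocorrelation(series, 150)
        assert zeros > 2

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(9)
        series = [rng.normal(size=400) for _ in range(20)]
        _, mean_abs, _, _ = ensemble_autocorrelation(series, 50)
        assert np.all(mean_abs[1:] < 3.0 / math.sqrt(400))

    def test_constant_series_excluded_with_warning(self):
        rng = np.random.default_rng(10)
        series = [np.ones(100), rng.normal(size=100), rng.normal(size=100)]
        with pytest.warns(UserWarning, match="constant"):
            lags, mean_abs, _, _ = ensemble_autocorrelation(series, 20)
        assert mean_abs.shape == (21,)

    def test_zero_crossing_counter(self):
        assert count_zero_crossings(np.array([1.0, 0.5, -0.5, -1.0])) == 1
        assert count_zero_crossings(np.array([1.0, -1.0, 1.0, -1.0])) == 3
        assert count_zero_crossings(np.array([1.0, 0.0, 1.0])) == 0


class TestArrestedClusters:
    def test_all_growing_empty(self):
        tree = four_leaf_tree()
        for n in tree.nodes:
            n.growth_rate = LAM
        assert arrested_clusters(tree) == []

    def test_all_arrested_single_cluster(self):
        tree = four_leaf_tree()
        for n in tree.nodes:
            n.growth_rate = 0.0
        assert arrested_clusters(tree) == [4]

    def test_toy_pattern_run_lengths(self):
        # depth-first arrest pattern 1,1,0,0,1,0 -> cluster sizes {2, 1}
        tree = six_leaf_arrest_tree()
        assert sorted(arrested_clusters(tree)) == [1, 2]

    def test_sizes_sum_to_arrested_count(self):
        cfg = m.SimulationConfig(seed=30, rates=m.RateParameters(k_t=5.0))
        tree = m.simulate_lineage(cfg)
        sizes = arrested_clusters(tree, cutoff=cfg.arrest_cutoff)
        n_arrested = sum(1 for n in tree.extant_nodes()
                         if n.growth_rate <= cfg.arrest_cutoff)
        assert sum(sizes) == n_arrested


class TestClusterSizeDistribution:
    def test_geometric_decay_recovered(self):
        # geometric sizes: P(c) ~ (1-p)^(c-1), i.e. b = -ln(1-p)
        rng = np.random.default_rng(11)
        p = 0.45
        sizes = rng.geometric(p, size=5000)
        dist = cluster_size_distribution([list(sizes)])
        assert dist.fit_b == pytest.approx(-math.log(1 - p), rel=0.1)
        assert dist.fit_r2 > 0.93  # rare large sizes add sampling scatter

    def test_empty_and_degenerate(self):
        dist = cluster_size_distribution([[]])
        assert dist.sizes.size == 0 and dist.fit_a is None
        dist = cluster_size_distribution([[1, 1, 2]])
        assert dist.fit_a is None  # fewer than 3 distinct sizes
        assert list(dist.sizes) == [1, 2]
        assert dist.normalized[0] == pytest.approx(1.0)

    def test_counts_pooled_across_simulations(self):
        dist = cluster_size_distribution([[1, 2], [2, 3], [1]])
        assert dict(zip(dist.sizes, dist.counts)) == {1: 2, 2: 2, 3: 1}


def mann_whitney_exact_oracle(a, b):
    """Full enumeration of the one-tailed (a shifted low) null distribution.

    U counts (a > b) pairs with ties at half weight; the p-value is the
    fraction of group relabelings with U at or below the observed value.
    """
    def u_stat(grp_a, grp_b):
        return sum(1 for x in grp_a for y in grp_b if x > y) + \
            0.5 * sum(1 for x in grp_a for y in grp_b if x == y)

    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = u_stat(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(grp_a, grp_b) <= u_obs + 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney_lineage([1, 2, 3], [10, 11, 12],
                                    alternative="less")
        assert p == pytest.approx(1 / math.comb(6, 3))  # = 0.05
        assert p == pytest.approx(
            mann_whitney_exact_oracle([1, 2, 3], [10, 11, 12]))

    @pytest.mark.parametrize("a, b", [
        ([3, 1, 4], [1, 5, 9]),
        ([2, 7], [1, 8, 2]),
        ([5], [5, 6, 7]),
    ])
    def test_matches_enumeration_on_small_groups(self, a, b):
        _, p = mann_whitney_lineage(a, b, alternative="less")
        assert p == pytest.approx(mann_whitney_exact_oracle(a, b), abs=1e-12)

    def test_identical_groups_near_half(self):
        _, p = mann_whitney_lineage([1.0, 2.0, 3.0, 4.0],
                                    [1.0, 2.0, 3.0, 4.0],
                                    alternative="less")
        assert 0.3 < p <= 0.75

    def test_degenerate_tied_singletons(self):
        u, p = mann_whitney_lineage([1.0], [1.0], alternative="less")
        assert 0 < p <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_lineage([], [1.0])


class TestEndToEndInvariants:
    def test_mi_nonnegative_on_simulated_pairs(self, mi_ensembles):
        rng = np.random.default_rng(12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for trees in mi_ensembles.values():
                est = mutual_information(sample_pairs(trees, rng=rng),
                                         rng=rng)
                assert est.mi_bits >= 0
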