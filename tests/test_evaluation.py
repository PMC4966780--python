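"""Benchmark statistics: set similarities, distance correlation,
grouped correlation, length-bias audit."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topoicsim import (
    GeneSetCollection,
    PairedSample,
    correlated_pairs,
    discriminating_power,
    distance_correlation,
    evaluate_collection,
    grouped_correlation,
    idp,
    interset_sim,
    intraset_sim,
    length_bias_audit,
    spearman_with_pvalue,
)

import oracles
from conftest import random_case


class TestSetStatistics:
    def test_intraset_single_gene(self):
        assert intraset_sim([[1.0]]) == 1.0

    def test_intraset_includes_self_pairs(self):
        m = [[1.0, 0.5], [0.5, 1.0]]
        assert intraset_sim(m) == pytest.approx(0.75)

    def test_intraset_matches_double_loop(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(4, 4))
        want = sum(m[i, j] for i in range(4) for j in range(4)) / 16
        assert intraset_sim(m) == pytest.approx(want)

    def test_interset(self):
        assert interset_sim([[1.0]]) == 1.0
        assert interset_sim(np.zeros((3, 2))) == 0.0
        rng = np.random.default_rng(1)
        m = rng.uniform(size=(3, 5))
        assert interset_sim(m) == pytest.approx(m.sum() / 15)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            intraset_sim(np.empty((0, 0)))

    def test_dp_identical_statistics(self):
        intra = pd.Series({"a": 0.6, "b": 0.6, "c": 0.6})
        inter = pd.DataFrame(0.6, index=list("abc"), columns=list("abc"))
        dp = discriminating_power(intra, inter)
        assert np.allclose(dp, 1.0)
        assert np.allclose(idp(intra, dp), 0.6)

    def test_dp_two_sets_is_ratio(self):
        intra = pd.Series({"a": 0.8, "b": 0.4})
        inter = pd.DataFrame(
            [[0.8, 0.2], [0.2, 0.4]], index=list("ab"), columns=list("ab")
        )
        dp = discriminating_power(intra, inter)
        assert dp["a"] == pytest.approx(0.8 / 0.2)
        assert dp["b"] == pytest.approx(0.4 / 0.2)

    def test_dp_random_three_sets_direct_formula(self):
        rng = np.random.default_rng(2)
        labels = list("abc")
        intra = pd.Series(rng.uniform(size=3), index=labels)
        raw = rng.uniform(size=(3, 3))
        inter = pd.DataFrame(
            (raw + raw.T) / 2, index=labels, columns=labels
        )
        for i, k in enumerate(labels):
            inter.loc[k, k] = intra[k]
        dp = discriminating_power(intra, inter)
        for k in labels:
            denom = sum(inter.loc[k, l] for l in labels if l != k)
            assert dp[k] == pytest.approx(2 * intra[k] / denom)

    def test_dp_single_set_raises(self):
        with pytest.raises(ValueError):
            discriminating_power(pd.Series({"a": 1.0}), pd.DataFrame([[1.0]]))

    def test_evaluate_collection_consistency(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(6)]
        raw = rng.uniform(size=(6, 6))
        sim = pd.DataFrame(
            (raw + raw.T) / 2 + np.eye(6), index=genes, columns=genes
        ).clip(upper=1.0)
        coll = GeneSetCollection(
            sets={"s1": genes[:2], "s2": genes[2:4], "s3": genes[4:]}
        )
        rep = evaluate_collection(sim, coll)
        assert np.allclose(rep.interset, rep.interset.T)
        assert np.allclose(np.diag(rep.interset), rep.intraset)
        # interset(S_k, S_k) equals intraset(S_k) exactly
        block = sim.loc[coll.sets["s1"], coll.sets["s1"]].to_numpy()
        assert rep.intraset["s1"] == pytest.approx(intraset_sim(block))
        assert np.allclose(rep.idp, rep.intraset * rep.dp)

    def test_collection_from_tsv(self):
        coll = GeneSetCollection.from_tsv("s1\tg1\ns1\tg2\ns2\tg3\n")
        assert coll.sets == {"s1": ["g1", "g2"], "s2": ["g3"]}
        with pytest.raises(ValueError):
            GeneSetCollection(sets={})


class TestDistanceCorrelation:
    def test_identical_samples_dcor_one(self):
        x = np.random.default_rng(0).normal(size=20)
        _, r = distance_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_constant_marginal_dcor_zero(self):
        x = np.arange(10.0)
        _, r = distance_correlation(x, np.ones(10))
        assert r == 0.0

    def test_four_point_triple_loop(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        y = np.array([2.0, 1.0, 5.0, 4.0])
        v, _ = distance_correlation(x, y)
        assert v == pytest.approx(oracles.dcov2_triple_loop(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.normal(size=(n, 2))
        y = rng.normal(size=(n, 3))
        v, _ = distance_correlation(x, y)
        assert v == pytest.approx(oracles.dcov2_triple_loop(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_range_and_invariances(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 2))
        y = rng.normal(size=(15, 2))
        _, r = distance_correlation(x, y)
        assert 0.0 <= r <= 1.0
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        _, r2 = distance_correlation(x @ rot + 3.0, y - 1.5)
        assert r2 == pytest.approx(r, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            distance_correlation([1.0], [2.0])
        with pytest.raises(ValueError):
            distance_correlation([1.0, 2.0], [1.0, 2.0, 3.0])


class TestGroupedCorrelation:
    def test_perfectly_correlated(self):
        sample = correlated_pairs(300, 1.0, n_clusters=3, seed=0)
        assert grouped_correlation(sample, n_groups=3) == pytest.approx(1.0)

    def test_independent_noise_missing_marker(self):
        rng = np.random.default_rng(1)
        sample = PairedSample(r=rng.normal(size=400), s=rng.normal(size=400))
        assert math.isnan(grouped_correlation(sample, n_groups=4))

    def test_mixture_recovers_cluster_correlation(self):
        sample = correlated_pairs(2000, 0.8, n_clusters=4, seed=2)
        got = grouped_correlation(sample, grouping="quantile", n_groups=4)
        assert got == pytest.approx(0.8, abs=0.1)

    def test_grid_grouping(self):
        sample = correlated_pairs(2000, 0.9, n_clusters=3, seed=3)
        got = grouped_correlation(sample, grouping="grid", n_groups=9)
        assert got == pytest.approx(0.9, abs=0.1)

    def test_custom_group_fn(self):
        sample = correlated_pairs(200, 0.95, n_clusters=2, seed=4)
        labels = (sample.r > np.median(sample.r)).astype(int)
        got = grouped_correlation(sample, group_fn=lambda s: labels, n_groups=2)
        assert got == pytest.approx(0.95, abs=0.15)


class TestSpearman:
    def test_exact_small_sample_matches_scipy_statistic(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r, p = spearman_with_pvalue(x, y)
        assert r == pytest.approx(stats.spearmanr(x, y).statistic)
        assert 0.0 <= p <= 1.0

    def test_exact_p_perfect_monotone(self):
        x = np.arange(5.0)
        r, p = spearman_with_pvalue(x, x**3)
        assert r == 1.0
        # two-sided exact: only the two perfect orderings reach |r| = 1
        assert p == pytest.approx(2 / math.factorial(5))

    def test_constant_inputs_ties_convention(self):
        r, p = spearman_with_pvalue(np.ones(6), np.arange(6.0))
        assert (r, p) == (0.0, 1.0)

    def test_large_sample_t_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r, p = spearman_with_pvalue(x, y)
        sr = stats.spearmanr(x, y)
        assert (r, p) == (pytest.approx(sr.statistic), pytest.approx(sr.pvalue))


class TestLengthBiasAudit:
    def test_constant_measure_r_zero(self):
        graph, _ = random_case(0, n_lo=12, n_hi=12)
        res = length_bias_audit(
            graph, lambda a, b: 0.5, sizes=range(1, 6), n_pairs=10, seed=0
        )
        assert res.spearman_r == 0.0 and res.p_value == 1.0

    def test_size_measure_r_one(self):
        graph, _ = random_case(1, n_lo=12, n_hi=12)
        res = length_bias_audit(
            graph, lambda a, b: float(len(a)), sizes=range(1, 6), n_pairs=5, seed=0
        )
        assert res.spearman_r == pytest.approx(1.0)

    def test_insufficient_terms_raises(self, chain):
        with pytest.raises(ValueError):
            length_bias_audit(chain, lambda a, b: 0.0, sizes=[5], n_pairs=2)

    def test_deterministic_under_seed(self):
        graph, ic = random_case(2, n_lo=12, n_hi=12)
        from topoicsim import make_topoicsim_group_measure

        fn = make_topoicsim_group_measure(graph, ic)
        r1 = length_bias_audit(graph, fn, sizes=range(1, 4), n_pairs=5, seed=9)
        r2 = length_bias_audit(graph, fn, sizes=range(1, 4), n_pairs=5, seed=9)
        assert r1.mean_scores == r2.mean_scores
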