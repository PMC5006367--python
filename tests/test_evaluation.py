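"""Fusion, random-pair sampling, ROC/AUC and empirical p-values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from diseasesim.evaluation import (
    empirical_pvalue, evaluate, iteration_seed, mednetsim, pvalue_report,
    roc_auc, roc_curve_points, sample_random_pairs,
)
from diseasesim.io import BenchmarkSet, SimilarityTable, canonical_pair
from oracles import auc_exhaustive


class TestMedNetSim:
    @pytest.mark.parametrize("med,net,expected", [
        (0.5, 0.4, 0.2), (0.9, 0.0, 0.0), (0.0, 0.7, 0.0), (1.0, 1.0, 1.0),
    ])
    def test_product_fusion(self, med, net, expected):
        assert mednetsim(med, net) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_the_smaller_factor(self, a, b):
        assert mednetsim(a, b) <= min(a, b) + 1e-15

    def test_negative_or_non_finite_rejected(self):
        for bad in ((-0.1, 0.5), (0.5, float("nan")), (float("inf"), 1.0)):
            with pytest.raises(ValueError):
                mednetsim(*bad)


class TestSampleRandomPairs:
    DISEASES = [f"d{i:02d}" for i in range(12)]

    def test_same_seed_gives_identical_list(self):
        a = sample_random_pairs(self.DISEASES, n=20, seed=5)
        b = sample_random_pairs(self.DISEASES, n=20, seed=5)
        assert a == b

    def test_pairs_are_distinct_canonical_non_degenerate(self):
        pairs = sample_random_pairs(self.DISEASES, n=30, seed=1)
        assert len(set(pairs)) == 30
        for a, b in pairs:
            assert a < b

    def test_exclusion_filter_brute_force(self):
        exclude = BenchmarkSet(pairs={("d00", "d01"), ("d02", "d03")})
        pairs = sample_random_pairs(self.DISEASES, n=50, exclude=exclude,
                                    seed=2)
        for pair in pairs:
            assert canonical_pair(*pair) not in exclude.pairs

    def test_requesting_more_than_eligible_errors_with_maximum(self):
        exclude = BenchmarkSet(pairs={("d00", "d01")})
        total = 12 * 11 // 2
        with pytest.raises(ValueError, match=str(total - 1)):
            sample_random_pairs(self.DISEASES, n=total, exclude=exclude,
                                seed=0)

    def test_dense_request_still_honors_exclusion(self):
        # asks for nearly every pair, exercising the permutation branch
        exclude = BenchmarkSet(pairs={("d00", "d01")})
        total = 12 * 11 // 2
        pairs = sample_random_pairs(self.DISEASES, n=total - 1,
                                    exclude=exclude, seed=3)
        assert len(set(pairs)) == total - 1
        assert ("d00", "d01") not in pairs


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_enumerated_four_cross_pairs(self):
        # (3>2)+(3>0)+(1>0)=3 of 4 cross pairs
        assert roc_auc([3, 1], [2, 0]) == pytest.approx(0.75)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_exhaustive_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 6, size=rng.integers(1, 40)).astype(float)
        neg = rng.integers(0, 6, size=rng.integers(1, 40)).astype(float)
        assert roc_auc(pos, neg) == pytest.approx(auc_exhaustive(pos, neg))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(1, 1, size=30)
        neg = rng.normal(0, 1, size=40)
        labels = np.r_[np.ones(30), np.zeros(40)]
        scores = np.r_[pos, neg]
        assert roc_auc(pos, neg) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_complement_identity(self):
        rng = np.random.default_rng(9)
        pos = rng.integers(0, 4, size=25).astype(float)
        neg = rng.integers(0, 4, size=30).astype(float)
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0)

    def test_curve_starts_at_origin_and_ends_at_one_one(self):
        points = roc_curve_points([0.9, 0.4], [0.5, 0.1])
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)
        fprs = [p[0] for p in points]
        assert fprs == sorted(fprs)


class TestEvaluate:
    DISEASES = [f"d{i:02d}" for i in range(14)]
    BENCH = BenchmarkSet(pairs={("d00", "d01"), ("d02", "d03"),
                                ("d04", "d05")})

    def test_membership_indicator_scores_perfect_auc(self):
        method = lambda a, b: 1.0 if (a, b) in self.BENCH else 0.0
        res = evaluate(method, self.BENCH, self.DISEASES, iterations=4,
                       n_random=20, seed=3)
        assert res.mean_auc == 1.0

    def test_constant_method_scores_half(self):
        res = evaluate(lambda a, b: 0.5, self.BENCH, self.DISEASES,
                       iterations=4, n_random=20, seed=3)
        assert res.mean_auc == 0.5

    def test_mean_equals_independently_recomputed_aucs(self):
        rng = np.random.default_rng(0)
        scores = {}

        def method(a, b):
            key = canonical_pair(a, b)
            if key not in scores:
                scores[key] = float(
                    np.random.default_rng(hash(key) % 2**32).random()
                )
            return scores[key]

        res = evaluate(method, self.BENCH, self.DISEASES, iterations=5,
                       n_random=15, seed=11)
        pos = [method(a, b) for a, b in sorted(self.BENCH.pairs)]
        recomputed = []
        for it in range(5):
            pairs = sample_random_pairs(self.DISEASES, n=15,
                                        exclude=self.BENCH,
                                        seed=iteration_seed(11, it))
            neg = [method(a, b) for a, b in pairs]
            recomputed.append(roc_auc(pos, neg))
        assert res.auc_per_iteration == pytest.approx(recomputed)
        assert res.mean_auc == pytest.approx(float(np.mean(recomputed)))

    def test_unscoreable_benchmark_disease_aborts_with_listing(self):
        def method(a, b):
            if a == "d04" or b == "d04":
                raise KeyError(a)
            return 0.5

        with pytest.raises(ValueError, match="d04"):
            evaluate(method, self.BENCH, self.DISEASES, iterations=2,
                     n_random=10, seed=0)


class TestEmpiricalPValue:
    def test_score_above_all_values_floors_at_one_over_n(self):
        dist = list(np.linspace(0, 1, 100))
        assert empirical_pvalue(2.0, dist) == pytest.approx(1 / 100)

    def test_score_at_distribution_minimum_gives_one(self):
        dist = [0.2, 0.5, 0.9]
        assert empirical_pvalue(0.2, dist) == 1.0

    def test_95th_percentile_of_thousand_values_is_related(self):
        dist = list(np.arange(1, 1001, dtype=float))
        score = 951.0  # exactly 50 of 1000 values are >= score
        p = empirical_pvalue(score, dist)
        assert p == pytest.approx(0.05)
        assert p <= 0.05

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(4)
        dist = rng.random(200)
        scores = np.sort(rng.random(50))
        ps = [empirical_pvalue(s, dist) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_distribution_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.5, [])


class TestPValueReport:
    def test_flags_follow_the_five_percent_rule(self):
        med = SimilarityTable({("a", "b"): 1.0, ("a", "c"): 0.1,
                               ("b", "c"): 0.2})
        net = SimilarityTable({("a", "b"): 0.1, ("a", "c"): 0.5,
                               ("b", "c"): 0.9})
        fused = SimilarityTable({("a", "b"): 0.1, ("a", "c"): 0.05,
                                 ("b", "c"): 0.18})
        report = pvalue_report(("b", "a"), med, net, fused)
        assert report.pair == ("a", "b")
        assert report.medsim_p == pytest.approx(1 / 3)
        assert report.netsim_p == pytest.approx(1.0)
        assert not report.related["medsim"]
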