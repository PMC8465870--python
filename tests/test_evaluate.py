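"""External validity measures: contingency, purity/precision/recall/F,
analytic bounds, repetition protocol and the direction comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from swaysom import evaluate
from swaysom.errors import InsufficientDataError, InvalidArgumentError


def table_from_counts(rows):
    """rows: list of dicts class->count, one per cluster."""
    return evaluate.ContingencyTable(
        counts=pd.DataFrame(rows).fillna(0).astype(int)
    )


def min_recall_brute(K, A, B):
    """Brute-force minimum cluster-averaged recall by full composition
    enumeration (feasible only for small classes)."""
    best = np.inf
    def comps(total, parts):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for tail in comps(total - head, parts - 1):
                yield (head,) + tail
    for a in comps(A, K):
        for b in comps(B, K):
            if any(ai + bi == 0 for ai, bi in zip(a, b)):
                continue
            recall = np.mean(
                [ai / A if ai >= bi else bi / B for ai, bi in zip(a, b)]
            )
            best = min(best, recall)
    return best


class TestContingency:
    def test_perfect_split_is_diagonal(self):
        t = evaluate.contingency([0] * 3 + [1] * 3, ["a"] * 3 + ["b"] * 3)
        assert np.array_equal(t.counts.to_numpy(), [[3, 0], [0, 3]])

    def test_single_cluster_single_row(self):
        t = evaluate.contingency([0] * 6, ["a"] * 3 + ["b"] * 3)
        assert t.counts.shape == (1, 2)
        assert t.n == 6

    def test_matches_hand_tally(self):
        assignment = [0, 1, 0, 1, 1, 0, 0]
        labels = ["x", "x", "y", "y", "x", "x", "y"]
        t = evaluate.contingency(assignment, labels)
        # cluster 0: x at 0,5; y at 2,6 -> (2,2); cluster 1: x at 1,4; y at 3
        assert np.array_equal(t.counts.to_numpy(), [[2, 2], [2, 1]])

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            evaluate.contingency([0, 1], ["a"])


class TestMeasures:
    def test_balanced_collapse_floors_purity_and_precision(self):
        t = table_from_counts([{"c1": 23, "c2": 23}])
        assert evaluate.purity(t) == 0.5
        assert evaluate.precision_avg(t) == 0.5

    def test_pure_and_complete_clustering_maxes_everything(self):
        t = table_from_counts([{"c1": 23, "c2": 0}, {"c1": 0, "c2": 23}])
        m = evaluate.external_measures(t)
        assert m.purity == m.precision == m.recall == m.f_measure == 1.0

    def test_symmetric_mixture_hand_value(self):
        t = table_from_counts([{"a": 15, "b": 8}, {"a": 8, "b": 15}])
        m = evaluate.external_measures(t)
        assert m.purity == pytest.approx(30 / 46)
        assert m.recall == pytest.approx(15 / 23)
        assert m.f_measure == pytest.approx(
            2 * (15 / 23) * (15 / 23) / (15 / 23 + 15 / 23)
        )

    def test_unbalanced_clusters_precision_hand_value(self):
        t = table_from_counts([{"a": 20, "b": 2}, {"a": 3, "b": 21}])
        assert evaluate.precision_avg(t) == pytest.approx(
            np.mean([20 / 22, 21 / 24])
        )

    def test_complete_singleton_class_cluster_recall_one(self):
        t = table_from_counts([{"a": 23, "b": 0}, {"a": 0, "b": 23}])
        per = evaluate.external_measures(t).per_cluster
        assert (per["recall_i"] == 1.0).all()

    def test_per_cluster_precision_equals_purity(self):
        t = table_from_counts([{"a": 9, "b": 3}, {"a": 2, "b": 11}])
        per = evaluate.external_measures(t).per_cluster
        # precision of a cluster is the same as its purity by construction
        assert (per["purity_i"] <= 1).all() and (per["purity_i"] >= 0.5).all()

    def test_purity_is_size_weighted_mean_of_cluster_precisions(self, rng):
        for _ in range(20):
            assignment = rng.integers(0, 4, 46)
            labels = np.repeat([1, 2], 23)
            t = evaluate.contingency(assignment, labels)
            m = evaluate.external_measures(t)
            weighted = float(
                (m.per_cluster["n_i"] / t.n * m.per_cluster["purity_i"]).sum()
            )
            assert m.purity == pytest.approx(weighted, abs=1e-12)

    def test_merging_two_clusters_never_increases_purity(self, rng):
        labels = np.repeat([1, 2], 23)
        for _ in range(20):
            assignment = rng.integers(0, 4, 46)
            if len(set(assignment.tolist())) < 2:
                continue
            before = evaluate.purity(evaluate.contingency(assignment, labels))
            merged = assignment.copy()
            present = sorted(set(merged.tolist()))
            merged[merged == present[1]] = present[0]
            after = evaluate.purity(evaluate.contingency(merged, labels))
            assert after <= before + 1e-12

    def test_majority_tie_goes_to_lower_class(self):
        t = table_from_counts([{"a": 5, "b": 5}])
        per = evaluate.external_measures(t).per_cluster
        assert per.loc[0, "majority_class"] == "a"


class TestMinBounds:
    @pytest.mark.parametrize("K,expected", [(2, 0.5), (4, 0.25), (6, 1 / 6)])
    def test_balanced_recall_floor_is_one_over_k(self, K, expected):
        b = evaluate.min_bounds(K, (23, 23))
        assert b.min_recall == pytest.approx(expected, abs=1e-12)
        assert b.min_purity == 0.5 and b.min_precision == 0.5
        assert b.max_all == 1.0

    @pytest.mark.parametrize("K,A,B", [(2, 5, 5), (3, 5, 5), (2, 4, 6), (3, 4, 6)])
    def test_recall_floor_matches_brute_force_enumeration(self, K, A, B):
        assert evaluate.min_bounds(K, (A, B)).min_recall == pytest.approx(
            min_recall_brute(K, A, B), abs=1e-12
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidArgumentError):
            evaluate.min_bounds(0, (23, 23))
        with pytest.raises(InvalidArgumentError):
            evaluate.min_bounds(50, (23, 23))

    def test_all_measures_respect_bounds_under_fuzzing(self, rng):
        labels = np.repeat([1, 2], 23)
        for K in (2, 3, 4):
            b = evaluate.min_bounds(K, (23, 23))
            for _ in range(30):
                assignment = rng.integers(0, K, 46)
                if len(set(assignment.tolist())) != K:
                    continue
                m = evaluate.external_measures(
                    evaluate.contingency(assignment, labels)
                )
                assert b.min_purity - 1e-12 <= m.purity <= 1.0
                assert b.min_precision - 1e-12 <= m.precision <= 1.0
                assert b.min_recall - 1e-12 <= m.recall <= 1.0
                assert 0.0 <= m.f_measure <= 1.0


class TestCompareDirections:
    def test_identical_samples_not_significant(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, _, p = evaluate.compare_directions(v, v)
        assert p > 0.9

    def test_mann_whitney_exact_small_sample(self):
        # all C(6,3)=20 rank splits; the two extreme orderings give p = 2/20
        name, _, p = evaluate.compare_directions(
            [1, 2, 3], [4, 5, 6], method="mannwhitney"
        )
        assert name == "mannwhitney"
        assert p == pytest.approx(0.1)

    def test_t_branch_for_normal_samples(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        name, _, _ = evaluate.compare_directions(a, b)
        assert name == "t"

    def test_power_against_two_sigma_shift(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            _, _, p = evaluate.compare_directions(a, b)
            hits += p < 0.05
        assert hits >= 9

    def test_too_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            evaluate.compare_directions([1.0], [2.0])


class TestRepeatPipeline:
    @staticmethod
    def _dummy_cluster_once(X, labels, K, seed):
        rng = np.random.default_rng(seed)
        t = evaluate.contingency(
            rng.integers(0, K, len(labels)) if K > 1 else np.zeros(len(labels)),
            labels,
        )
        return evaluate.external_measures(t)

    def test_single_repetition_has_zero_iqr(self):
        labels = np.repeat([1, 2], 10)
        X = np.zeros((20, 2))
        per = evaluate.repeat_pipeline(
            X, labels, 2, self._dummy_cluster_once, n_reps=1, master_seed=0
        )
        assert len(per) == 1
        summary = evaluate.summarize_measures(per)
        assert (summary["iqr"] == 0).all()

    def test_deterministic_given_master_seed(self):
        labels = np.repeat([1, 2], 10)
        X = np.zeros((20, 2))
        a = evaluate.repeat_pipeline(
            X, labels, 2, self._dummy_cluster_once, n_reps=5, master_seed=3
        )
        b = evaluate.repeat_pipeline(
            X, labels, 2, self._dummy_cluster_once, n_reps=5, master_seed=3
        )
        pd.testing.assert_frame_equal(a, b)
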