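"""Negative sampling, folds, metrics, over-smoothing diagnostics, Wilcoxon."""

import warnings

import numpy as np
import pytest
from scipy import stats

import dtismooth as dm
from dtismooth.evaluation import SamplingPlan


def auc_pairwise_oracle(labels, scores):
    """P(random positive outranks random negative), ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def aupr_enumeration_oracle(labels, scores):
    """PR-curve integration by direct enumeration over distinct thresholds.

    AP = sum over thresholds of (recall step) * precision, with tied scores
    entering the ranking together.
    """
    total_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        called = scores >= thr
        tp = int((labels[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestNegativeSampling:
    def test_count_and_disjointness(self):
        h, _, _ = dm.generate_hbin(dm.SyntheticConfig(n_drugs=10, n_targets=8, g=2, seed=1))
        negs = dm.sample_negatives(h, SamplingPlan(ratio=2, seed=0))
        assert len(negs) == 2 * h.n_edges
        assert not set(negs) & h.edges
        assert len(set(negs)) == len(negs)

    def test_ratio_ten(self):
        h = dm.build_hbin(
            [f"d{i}" for i in range(20)],
            [f"t{j}" for j in range(20)],
            [(f"d{i}", f"t{i}") for i in range(10)],
        )
        negs = dm.sample_negatives(h, SamplingPlan(ratio=10, seed=3))
        assert len(negs) == 100
        assert not set(negs) & h.edges

    def test_complete_bipartite_degenerate(self):
        h = dm.build_hbin(
            ["d1", "d2"], ["t1"], [("d1", "t1"), ("d2", "t1")]
        )
        with pytest.warns(UserWarning, match="no non-interacting"):
            assert dm.sample_negatives(h, SamplingPlan(ratio=1, seed=0)) == []

    def test_universe_exhaustion_warns(self):
        h = dm.build_hbin(["d1", "d2"], ["t1", "t2"],
                          [("d1", "t1"), ("d1", "t2"), ("d2", "t1")])
        with pytest.warns(UserWarning, match="non-edges"):
            negs = dm.sample_negatives(h, SamplingPlan(ratio=10, seed=0))
        assert negs == [(1, 3)]  # the single non-edge (d2, t2)

    def test_never_intersects_edges_across_seeds(self):
        h, _, _ = dm.generate_hbin(dm.SyntheticConfig(n_drugs=8, n_targets=6, g=2, seed=5))
        for seed in range(200):
            negs = dm.sample_negatives(h, SamplingPlan(ratio=1, seed=seed))
            assert not set(negs) & h.edges


class TestFolds:
    def test_equal_sizes_partition_determinism(self):
        labels = np.array([1] * 50 + [0] * 50)
        plan = dm.make_folds(labels, n_folds=10, seed=4)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert (sizes == 10).all()
        plan2 = dm.make_folds(labels, n_folds=10, seed=4)
        assert np.array_equal(plan.assignment, plan2.assignment)

    def test_stratification_within_one_pair(self):
        labels = np.array([1] * 37 + [0] * 63)
        plan = dm.make_folds(labels, n_folds=10, seed=0)
        for fold in range(10):
            mask = plan.assignment == fold
            n_pos = labels[mask].sum()
            expected = 37 * mask.sum() / 100
            assert abs(n_pos - expected) <= 1

    def test_invalid_fold_counts(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            dm.make_folds(labels, n_folds=1)
        with pytest.raises(ValueError):
            dm.make_folds(labels, n_folds=5)


class TestMetrics:
    def test_symmetric_confusion_case(self):
        # TP=8, FP=2, FN=2 at cutoff 0.5 -> P = R = F1 = 0.8
        labels = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        scores = np.array([0.9] * 10 + [0.1] * 10)
        rep = dm.compute_metrics(labels, scores, cutoff=0.5)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (8, 2, 2, 8)
        assert rep.precision == rep.recall == rep.f1 == 0.8

    def test_perfect_separation(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        rep = dm.compute_metrics(labels, scores)
        assert rep.auc == 1.0 and rep.aupr == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=2000)
        scores = rng.random(2000)
        rep = dm.compute_metrics(labels, scores)
        assert abs(rep.auc - 0.5) < 0.05

    def test_f1_zero_convention(self):
        labels = np.array([1, 0])
        scores = np.array([0.1, 0.2])  # nothing called
        rep = dm.compute_metrics(labels, scores)
        assert rep.f1 == 0.0

    def test_single_class_reported_undefined(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = dm.compute_metrics(np.array([1, 1]), np.array([0.6, 0.7]))
        assert np.isnan(rep.auc) and np.isnan(rep.aupr)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_independent_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(n), 2)  # ties likely
        rep = dm.compute_metrics(labels, scores)
        assert rep.auc == pytest.approx(auc_pairwise_oracle(labels, scores), abs=1e-9)
        assert rep.aupr == pytest.approx(
            aupr_enumeration_oracle(labels, scores), abs=1e-9
        )


class TestMad:
    def test_identical_rows_zero(self):
        assert dm.mad(np.tile([1.0, 2.0], (5, 1))) == pytest.approx(0.0)

    def test_orthogonal_rows_one(self):
        assert dm.mad(np.eye(2)) == pytest.approx(1.0)

    def test_three_row_hand_computation(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1 / np.sqrt(2), 1 / np.sqrt(2)]])
        d01, d02 = 1.0, 1 - 1 / np.sqrt(2)
        expected = np.mean(
            [(d01 + d02) / 2, (d01 + d02) / 2, (d02 + d02) / 2]
        )
        assert dm.mad(X) == pytest.approx(expected)

    def test_scale_invariance_and_zero_rows(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 4))
        scaled = X * rng.uniform(0.5, 3.0, size=(10, 1))
        assert dm.mad(scaled) == pytest.approx(dm.mad(X))
        with pytest.warns(UserWarning, match="zero rows"):
            assert dm.mad(np.vstack([X, np.zeros((1, 4))])) == pytest.approx(dm.mad(X))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            dm.mad(np.ones((1, 3)))


class TestIqr:
    def test_constant_vector(self):
        assert dm.iqr_dispersion(np.full(10, 3.3)) == 0.0

    def test_linear_interpolation_quartiles(self):
        assert dm.iqr_dispersion(np.arange(1.0, 101.0)) == pytest.approx(49.5)

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        v = rng.random(50)
        assert dm.iqr_dispersion(-2.5 * v) == pytest.approx(2.5 * dm.iqr_dispersion(v))

    def test_vector_set_mean_std(self):
        rows = np.vstack([np.arange(1.0, 101.0), np.arange(1.0, 101.0)])
        mean, std = dm.iqr_dispersion(rows)
        assert mean == pytest.approx(49.5) and std == pytest.approx(0.0)

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            dm.iqr_dispersion(np.array([1.0, 2.0, 3.0]))


class TestWilcoxon:
    def test_shifted_pairs_significant(self):
        rng = np.random.default_rng(0)
        b = rng.random(10)
        assert dm.paired_wilcoxon(b + 0.3, b) < 0.05

    def test_identical_pairs_undefined(self):
        with pytest.warns(UserWarning, match="zero"):
            assert np.isnan(dm.paired_wilcoxon(np.ones(6), np.ones(6)))

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(12), rng.random(12)
        assert dm.paired_wilcoxon(a, b) == pytest.approx(
            stats.wilcoxon(a, b).pvalue
        )

    def test_null_calibration(self):
        # same-distribution pairs: rejection rate at alpha=0.05 stays near 5%
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            rejections += dm.paired_wilcoxon(a, b) < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_length_validation(self):
        with pytest.raises(ValueError):
            dm.paired_wilcoxon(np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            dm.paired_wilcoxon(np.ones(6), np.ones(7))


class TestCrossValidate:
    def test_one_fold_rejected(self):
        h, _, _ = dm.generate_hbin(dm.SyntheticConfig(n_drugs=8, n_targets=6, g=2, seed=0))
        C = np.random.default_rng(0).random((14, 4))
        with pytest.raises(ValueError):
            dm.cross_validate(h, C, n_folds=1)

    def test_reports_have_fold_structure(self):
        h, _, _ = dm.generate_hbin(
            dm.SyntheticConfig(n_drugs=12, n_targets=10, g=2, seed=2)
        )
        rng = np.random.default_rng(1)
        C = rng.random((22, 6))
        res = dm.cross_validate(
            h, C, n_folds=3,
            gbdt=dm.GbdtConfig(n_trees=10),
            ndls=dm.NdlsConfig(epsilon=0.05),
        )
        assert len(res["folds"]) == 3
        assert 0.0 <= res["mean"]["auc"] <= 1.0
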