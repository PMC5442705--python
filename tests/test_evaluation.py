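"""ROC curves, AUC oracle agreement, bootstrap CIs and confusion matching."""

import numpy as np
import pandas as pd
import pytest

from dtwscore import confusion, roc_curve, sensitivity_ci
from dtwscore.exceptions import ValidationError


def pair_count_auc(scores, labels):
    """Independent AUC oracle: fraction of (positive, negative) pairs
    ordered correctly, ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        c = roc_curve([1, 1, 0, 0], [1, 1, 0, 0])
        assert c.auc == 1.0

    def test_uninformative(self):
        c = roc_curve([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1])
        assert c.auc == 0.5

    def test_worked_example(self):
        c = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert c.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        c = roc_curve(scores, labels)
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        scores = rng.integers(0, 10, n).astype(float)  # many ties
        labels = (rng.random(n) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert roc_curve(scores, labels).auc == pytest.approx(
            pair_count_auc(scores, labels)
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = (scores + rng.normal(size=80) > 0).astype(int)
        a = roc_curve(scores, labels).auc
        b = roc_curve(np.exp(scores), labels).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            roc_curve([1.0, 2.0], [1, 1])


class TestSensitivityCI:
    def test_perfect_separation_interval(self):
        scores = np.array([5.0] * 10 + [1.0] * 10)
        labels = np.array([1] * 10 + [0] * 10)
        ci = sensitivity_ci(scores, labels, (0.5, 0.9), n_boot=200, seed=0)
        assert (ci["lower"] == 1.0).all() and (ci["upper"] == 1.0).all()

    def test_percentile_contract(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
        labels = np.array([1] * 50 + [0] * 50)
        ci = sensitivity_ci(scores, labels, (0.8, 0.9), n_boot=300, seed=2)
        assert ((ci["lower"] <= ci["sensitivity"]) & (ci["sensitivity"] <= ci["upper"])).all()
        assert ((ci[["lower", "upper"]] >= 0) & (ci[["lower", "upper"]] <= 1)).all().all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(2, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        a = sensitivity_ci(scores, labels, (0.9,), n_boot=100, seed=7)
        b = sensitivity_ci(scores, labels, (0.9,), n_boot=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_interval_width_shrinks_with_n(self):
        def width(n, seed=11):
            rng = np.random.default_rng(seed)
            scores = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
            labels = np.array([1] * n + [0] * n)
            ci = sensitivity_ci(scores, labels, (0.9,), n_boot=300, seed=seed)
            return float(ci["upper"][0] - ci["lower"][0])

        assert width(800) < width(100)

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError, match="2 members"):
            sensitivity_ci([1.0, 2.0, 3.0], [1, 0, 0], (0.9,), n_boot=10, seed=0)

    def test_coverage_on_gaussian_simulation(self):
        """95% intervals cover the large-sample true sensitivity in most
        replicates (two-class normal shift, means 0 and 2)."""
        from scipy import stats

        spec = 0.9
        # true sensitivity at specificity 0.9: P(N(2,1) > z_{0.9})
        true_sens = 1 - stats.norm.cdf(stats.norm.ppf(spec) - 2.0)
        rng = np.random.default_rng(2718)
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            pos = rng.normal(2, 1, 200)
            neg = rng.normal(0, 1, 200)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * 200 + [0] * 200)
            ci = sensitivity_ci(
                scores, labels, (spec,), n_boot=250,
                seed=int(rng.integers(2**31)),
            )
            if ci["lower"][0] <= true_sens <= ci["upper"][0]:
                covered += 1
        assert covered / n_rep >= 0.90


class TestConfusion:
    def test_identity(self):
        table, acc = confusion([0, 0, 1, 1], [0, 0, 1, 1])
        assert acc == 1.0
        assert np.array_equal(np.diag(table.to_numpy()), [2, 2])

    def test_label_swap_invariance(self):
        truth = np.array([0, 0, 1, 1, 1])
        table, acc = confusion(1 - truth, truth)
        assert acc == 1.0

    def test_random_assignment_near_half(self):
        rng = np.random.default_rng(12)
        truth = np.repeat([0, 1], 500)
        assign = rng.integers(0, 2, 1000)
        _, acc = confusion(assign, truth)
        assert 0.45 <= acc <= 0.58  # matching picks the better permutation

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            confusion([0, 1], [0, 1, 1])
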