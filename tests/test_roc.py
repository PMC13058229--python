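"""ROC/DeLong contracts: exhaustive pair-counting oracle, rank invariances,
variance behaviour, paired test degeneracies, and operating-point rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bipolar_rf.errors import DegenerateOutcomeError, SchemaError
from bipolar_rf.roc import (
    delong_paired_test,
    operating_point,
    paired_auc_variance,
    roc_auc,
)


def auc_by_pair_counting(scores, labels):
    """Brute-force AUC: concordant pairs + half ties over n_pos * n_neg."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.delong_variance == 0.0
        assert r.ci95 == (1.0, 1.0)

    def test_all_ties_is_chance(self):
        r = roc_auc([3.0] * 8, [0, 1] * 4)
        assert r.auc == 0.5
        assert r.ci95 == (0.5, 0.5)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            roc_auc([1.0, 2.0], [1, 1])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        labels = np.zeros(n, int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        # coarse grid forces ties
        scores = rng.integers(0, 6, n).astype(float)
        if labels.min() == labels.max():
            return
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_by_pair_counting(scores, labels), abs=1e-12
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = (rng.uniform(size=30) < 0.4).astype(int)
        if labels.min() == labels.max():
            return
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(2.0 * scores) + 5, labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.delong_variance == pytest.approx(b.delong_variance, rel=1e-9)

    def test_negated_scores_mirror_auc(self, rng):
        scores = rng.normal(size=40)  # continuous: no ties
        labels = (rng.uniform(size=40) < 0.5).astype(int)
        assert roc_auc(-scores, labels).auc == pytest.approx(
            1.0 - roc_auc(scores, labels).auc, abs=1e-12
        )

    def test_variance_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        variances = []
        for n in (50, 500, 5000):
            labels = (rng.uniform(size=n) < 0.3).astype(int)
            scores = rng.normal(size=n) + labels  # fixed signal
            variances.append(roc_auc(scores, labels).delong_variance)
        assert variances[0] > variances[1] > variances[2]


class TestPairedTest:
    def test_identical_scores_exact_tie(self, rng):
        s = rng.normal(size=25)
        y = (rng.uniform(size=25) < 0.4).astype(int)
        z, p = delong_paired_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_gives_zero_difference(self, rng):
        s = rng.normal(size=25)
        y = (rng.uniform(size=25) < 0.4).astype(int)
        z, p = delong_paired_test(s, np.tanh(s) * 3 + 1, y)
        assert p == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(SchemaError):
            delong_paired_test([1.0, 2.0], [1.0], [0, 1])

    def test_detects_a_real_difference(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 300)
        informative = rng.normal(size=600) + 1.5 * y
        noise = rng.normal(size=600)
        z, p = delong_paired_test(informative, noise, y)
        assert z > 3 and p < 0.01

    def test_variance_close_to_bootstrap_at_small_n(self, rng):
        """Paired DeLong variance vs a stratified case-resampling bootstrap."""
        n = 12
        y = np.array([1] * 5 + [0] * 7)
        a = rng.normal(size=n) + 1.2 * y
        b = 0.6 * a + rng.normal(size=n)
        var_delong = paired_auc_variance(a, b, y)

        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        diffs = []
        for _ in range(10_000):
            idx = np.concatenate([rng.choice(pos, len(pos)),
                                  rng.choice(neg, len(neg))])
            diffs.append(
                auc_by_pair_counting(a[idx], y[idx])
                - auc_by_pair_counting(b[idx], y[idx])
            )
        var_boot = float(np.var(diffs, ddof=1))
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestOperatingPoint:
    def test_perfect_scores_youden(self):
        t, sens, spec = operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0

    def test_all_tied_scores_degenerate_to_all_negative(self):
        # documented tie-break: prefer specificity
        _, sens, spec = operating_point([2.0] * 6, [0, 1] * 3)
        assert (sens, spec) == (0.0, 1.0)

    def test_matches_exhaustive_scan(self, rng):
        scores = rng.normal(size=20)
        labels = (rng.uniform(size=20) < 0.45).astype(int)
        t, sens, spec = operating_point(scores, labels)
        best_j = max(
            np.mean(scores[labels == 1] >= c) + np.mean(scores[labels == 0] < c) - 1
            for c in np.r_[scores, scores.max() + 1]
        )
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_probability_half_rule(self):
        t, sens, spec = operating_point([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1],
                                        rule="prob0.5")
        assert t == 0.5 and sens == 0.5 and spec == 0.5


def test_auc_agrees_with_sklearn(rng):
    sk = pytest.importorskip("sklearn.metrics")
    scores = rng.normal(size=200)
    labels = (rng.uniform(size=200) < 0.35).astype(int)
    assert roc_auc(scores, labels).auc == pytest.approx(
        sk.roc_auc_score(labels, scores), abs=1e-12
    )
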