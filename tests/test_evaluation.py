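"""Statistical evaluation: AUC, bootstrap, Youden, survival, NNT."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mumo import evaluation as ev


# -- brute-force oracles ----------------------------------------------------

def auc_pairs_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    scores = np.asarray(scores); labels = np.asarray(labels)
    best, best_t = -np.inf, None
    for t in sorted(set(scores)):
        tpr = ((scores >= t) & (labels == 1)).sum() / (labels == 1).sum()
        fpr = ((scores >= t) & (labels == 0)).sum() / (labels == 0).sum()
        if tpr - fpr > best + 1e-15:
            best, best_t = tpr - fpr, t
    return best_t


def logrank_oracle(times, events, group):
    """Mantel–Haenszel O-E/V sums, straight-line."""
    times = np.asarray(times, float); events = np.asarray(events, bool)
    group = np.asarray(group, bool)  # True = group A
    O = E = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & group).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ((0.9, 0.8, 0.3, 0.2), (1, 1, 0, 0), 1.0),
        ((0.2, 0.9, 0.6, 0.4), (1, 0, 1, 0), 0.25),
        ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 0.5),
    ])
    def test_worked_examples(self, scores, labels, expected):
        assert ev.auc(scores, labels) == pytest.approx(expected)

    def test_matches_pair_enumeration_and_sklearn(self, rng):
        for _ in range(100):
            n = rng.integers(4, 15)
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            got = ev.auc(scores, labels)
            assert got == pytest.approx(auc_pairs_oracle(scores, labels), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.auc([0.1, 0.2], [1, 1])


class TestBootstrapCI:
    def test_perfect_separation_degenerate_ci(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]
        labels = [1, 1, 1, 0, 0, 0]
        assert ev.bootstrap_ci(scores, labels, B=100, seed=0) == (1.0, 1.0)

    def test_seeded_determinism(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = ev.bootstrap_ci(scores, labels, B=200, seed=5)
        assert a == ev.bootstrap_ci(scores, labels, B=200, seed=5)

    def test_ci_contains_point_estimate(self, rng):
        scores = rng.uniform(size=80)
        labels = (scores + rng.normal(0, 0.4, 80) > 0.5).astype(int)
        lo, hi = ev.bootstrap_ci(scores, labels, B=300, seed=1)
        assert lo <= ev.auc(scores, labels) <= hi

    def test_null_coverage(self):
        """Under the null (scores independent of labels) the 95% CI should
        cover 0.5 in the vast majority of simulated datasets."""
        rng = np.random.default_rng(42)
        covered = 0
        n_sets = 60
        for _ in range(n_sets):
            scores = rng.uniform(size=100)
            labels = rng.integers(0, 2, size=100)
            if labels.min() == labels.max():
                covered += 1
                continue
            lo, hi = ev.bootstrap_ci(scores, labels, B=200,
                                     seed=int(rng.integers(2 ** 31)))
            covered += lo <= 0.5 <= hi
        assert covered >= round(0.85 * n_sets)


class TestYouden:
    def test_worked_example(self):
        t = ev.youden_threshold((0.1, 0.2, 0.6, 0.8), (0, 0, 1, 1))
        assert t == 0.6

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ev.youden_threshold([0.1, 0.2], [1, 1])

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = rng.integers(4, 20)
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert ev.youden_threshold(scores, labels) == \
                pytest.approx(youden_oracle(scores, labels))


class TestSurvival:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [True] * 8
        scores = [1, 1, 1, 1, 0, 0, 0, 0]
        res = ev.stratify_and_survival(scores, 0.5, times, events)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-9)

    def test_four_subject_worked_example(self):
        """Group A events at (1, 2), group B at (3, 4): chi2 ~ 2.88."""
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True] * 4
        scores = [1.0, 1.0, 0.0, 0.0]  # A = high-risk
        res = ev.stratify_and_survival(scores, 0.5, times, events)
        oracle = logrank_oracle(times, events, [True, True, False, False])
        assert oracle == pytest.approx(2.882, abs=0.01)
        assert res.logrank_chi2 == pytest.approx(oracle, abs=0.01)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        times = np.sort(rng.integers(1, 30, size=12)).astype(float)
        scores = np.r_[np.ones(6), np.zeros(6)]
        res = ev.stratify_and_survival(scores, 0.5, np.r_[times[:6], times[6:]],
                                       np.ones(12, dtype=bool))
        km = res.km_curves["high"]
        grp = times[:6]
        for t in km.index[1:]:
            assert km.loc[t].iloc[0] == pytest.approx((grp > t).mean())

    def test_all_censored_km_flat_median_undefined(self):
        scores = [1, 1, 0, 0]
        res = ev.stratify_and_survival(scores, 0.5, [0.1] * 4, [False] * 4)
        assert np.isinf(res.median_survival["high"])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            ev.stratify_and_survival([1, 1], 0.5, [1, 2], [True, True])


class TestNNT:
    def test_worked_example(self):
        groups = ["low"] * 10 + ["high"] * 8
        flags = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 6
        assert ev.nnt(groups, flags) == pytest.approx(1 / 0.55, abs=1e-3)

    def test_perfect_separation(self):
        assert ev.nnt(["low", "low", "high"], [1, 1, 0]) == pytest.approx(1.0)

    def test_equal_rates_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ev.nnt(["low", "high"], [1, 1])

    def test_swapped_groups_flip_sign(self):
        groups = ["low"] * 4 + ["high"] * 4
        flags = [1, 1, 1, 0, 1, 0, 0, 0]
        swapped = ["high"] * 4 + ["low"] * 4
        assert ev.nnt(groups, flags) == pytest.approx(-ev.nnt(swapped, flags))


class TestEvaluateScores:
    def test_report_invariants(self, rng):
        scores = rng.uniform(size=60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        rep = ev.evaluate_scores(scores, labels, B=200, seed=0)
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
        assert set(rep.groups) <= {"high", "low"}
        assert rep.n == 60
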