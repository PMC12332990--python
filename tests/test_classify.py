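import numpy as np
import pytest

from adrenalct.classify import (
    confusion_at_threshold,
    delong_test,
    fit_classifiers,
    roc_auc,
    youden_threshold,
)


# -- independent oracles ----------------------------------------------------

def brute_auc(scores, labels):
    """Exhaustive concordant-pair counting with half-credit for ties."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels):
    scores = np.asarray(scores, float)
    y = np.asarray(labels, int)
    best = (-np.inf, None)
    for t in np.concatenate([[np.inf], np.unique(scores)[::-1]]):
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t < best[1]):
            best = (j, t)
    return best[1], best[0]


class TestRocAuc:
    def test_example_075(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == 0.75  # 3 of 4 pairs concordant

    def test_perfect_separation(self):
        roc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert roc.auc == 0.5

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_auc_in_ci(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            roc = roc_auc(rng.random(n), y)
            assert roc.ci95[0] <= roc.auc <= roc.ci95[1]

    def test_curve_monotone(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        roc = roc_auc(rng.random(50), y)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_equivalence_with_pair_counting(self, rng):
        # 200 random score sets, exact equality including ties
        for _ in range(200):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)  # induce ties
            assert roc_auc(scores, y).auc == pytest.approx(
                brute_auc(scores, y), abs=1e-12
            )


class TestYouden:
    def test_example_tie_broken_low(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        t, j = youden_threshold(roc)
        assert j == pytest.approx(0.5)
        assert t == pytest.approx(0.35)  # tie with 0.8 broken toward lower

    def test_perfect_separation(self):
        roc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        _, j = youden_threshold(roc)
        assert j == pytest.approx(1.0)

    def test_brute_force_equivalence(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)
            t, j = youden_threshold(roc_auc(scores, y))
            bt, bj = brute_youden(scores, y)
            assert j == pytest.approx(bj, abs=1e-12)
            assert t == pytest.approx(bt, abs=1e-12)


class TestConfusion:
    def test_left_validation_reconstruction(self):
        # printed composition: P=55, N=78, TP=46, TN=63 -> 109/133 correct
        scores = np.concatenate([np.ones(46), np.zeros(9), np.ones(15), np.zeros(63)])
        labels = np.concatenate([np.ones(55), np.zeros(78)]).astype(int)
        cm = confusion_at_threshold(scores, labels, 0.5)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (46, 9, 15, 63)
        assert cm.accuracy * 100 == pytest.approx(109 / 133 * 100)
        assert round(cm.accuracy * 100, 2) == 81.95

    def test_threshold_below_all(self, rng):
        y = np.array([0, 1, 0, 1])
        cm = confusion_at_threshold([0.2, 0.4, 0.6, 0.8], y, -1.0)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_threshold_above_all(self):
        y = np.array([0, 1, 0, 1])
        cm = confusion_at_threshold([0.2, 0.4, 0.6, 0.8], y, 2.0)
        assert cm.sensitivity == 0.0 and cm.specificity == 1.0

    def test_accuracy_identity(self, rng):
        # accuracy = (sens*P + spec*N) / (P+N) identically
        for _ in range(50):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[:2] = [0, 1]
            s = rng.random(n)
            cm = confusion_at_threshold(s, y, rng.random())
            P, N = (y == 1).sum(), (y == 0).sum()
            assert cm.accuracy == pytest.approx(
                (cm.sensitivity * P + cm.specificity * N) / (P + N), abs=1e-12
            )


class TestDelong:
    def test_self_comparison_degenerate(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        res = delong_test(s, s, y)
        assert res.auc_difference == 0.0
        assert res.p_value == 1.0 and res.degenerate

    def test_null_type_one_error_small(self, rng):
        # 200 replicates at n=60 for speed; full check in acceptance suite
        rejections = 0
        for _ in range(200):
            y = np.array([0, 1] * 30)
            a, b = rng.random(60), rng.random(60)
            if delong_test(a, b, y).p_value < 0.05:
                rejections += 1
        assert rejections / 200 < 0.12

    def test_bootstrap_oracle_agreement(self, rng):
        # paired bootstrap p on one toy set within 0.05 of the DeLong p
        n = 80
        y = np.array([0, 1] * (n // 2))
        signal = y + rng.normal(0, 1.2, n)
        a = signal + rng.normal(0, 0.4, n)
        b = 0.8 * signal + rng.normal(0, 0.6, n)
        res = delong_test(a, b, y)
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            auc_a = roc_auc(a[idx], y[idx]).auc
            auc_b = roc_auc(b[idx], y[idx]).auc
            diffs.append(auc_a - auc_b)
        diffs = np.asarray(diffs)
        observed = res.auc_a - res.auc_b
        # normal-theory bootstrap p for H0: diff = 0
        from scipy.stats import norm

        p_boot = 2 * norm.sf(abs(observed) / diffs.std(ddof=1))
        assert abs(res.p_value - p_boot) < 0.05

    def test_unpaired_variance_larger_for_correlated_scores(self, rng):
        y = np.array([0, 1] * 40)
        base = y + rng.normal(0, 1, 80)
        a = base + rng.normal(0, 0.2, 80)
        b = base + rng.normal(0, 0.2, 80)
        paired = delong_test(a, b, y, paired=True)
        unpaired = delong_test(a, b, y, paired=False)
        assert paired.variance < unpaired.variance

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3, 0.4], [1, 1])


class TestFitClassifiers:
    def test_separable_cohort(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (30, 3)), rng.normal(2, 0.3, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        comp = fit_classifiers(X, y, X, y, seed=0)
        assert comp.best.roc.auc == 1.0

    def test_unknown_model(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="supported"):
            fit_classifiers(X, y, X, y, model_set=("magic_forest",))

    def test_determinism(self, rng):
        X = rng.normal(size=(40, 4))
        y = (X[:, 0] > 0).astype(int)
        a = fit_classifiers(X[:30], y[:30], X[30:], y[30:], seed=7)
        b = fit_classifiers(X[:30], y[:30], X[30:], y[30:], seed=7)
        assert a.selected == b.selected
        np.testing.assert_array_equal(a.best.valid_scores, b.best.valid_scores)

    def test_label_permuted_null_band(self):
        # selected (max over models) validation AUC on permuted labels stays
        # within the null band; 20 seeds, n=200
        model_set = ("random_forest", "logistic_regression", "knn", "naive_bayes")
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 5))
            y = r.permutation(np.array([0, 1] * 100))
            comp = fit_classifiers(
                X[:140], y[:140], X[140:], y[140:], model_set=model_set, seed=seed
            )
            aucs.append(comp.best.roc.auc)
        assert all(0.4 <= a <= 0.75 for a in aucs), aucs
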