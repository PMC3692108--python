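import numpy as np
import pytest
from scipy import stats

from biosimgen import (FeatureMatrix, MarginalSpec, classification_metrics,
                       compare_sets, feature_combination_search,
                       fit_correlation_model, make_correlated_features,
                       mardia_test, normality_tests, simulate_features,
                       spearman_matrix, train_classifier)


def _fm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j + 1}" for j in range(values.shape[1])]
    return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], names, values)


class TestSpearmanMatrix:
    def test_monotone_invariance(self, rng):
        x = rng.normal(size=200)
        rho = spearman_matrix(_fm(np.column_stack([x, np.exp(x)])))
        assert rho[0, 1] == pytest.approx(1.0)

    def test_antitone(self, rng):
        x = rng.normal(size=200)
        rho = spearman_matrix(_fm(np.column_stack([x, -x])))
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_tied_toy_against_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([3.0, 3.0, 5.0, 6.0])
        ranks_x = stats.rankdata(x)  # average ranks
        ranks_y = stats.rankdata(y)
        expected = np.corrcoef(ranks_x, ranks_y)[0, 1]
        rho = spearman_matrix(_fm(np.column_stack([x, y])))
        assert rho[0, 1] == pytest.approx(expected)

    def test_constant_column_flagged_nan(self):
        vals = np.column_stack([np.arange(10.0), np.ones(10)])
        rho = spearman_matrix(_fm(vals))
        assert np.isnan(rho[0, 1])


class TestNormality:
    def test_normal_sample_flagged_normal(self):
        hits = 0
        for rep in range(10):
            x = np.random.default_rng(100 + rep).normal(size=1000)
            res = normality_tests(_fm(x[:, None]))
            hits += res["features"]["f1"]["normal"]
        assert hits >= 8

    def test_exponential_flagged_non_normal(self):
        x = np.random.default_rng(5).exponential(size=5000)
        res = normality_tests(_fm(x[:, None]))
        assert not res["features"]["f1"]["normal"]

    def test_bivariate_normal_mardia(self):
        hits = 0
        for rep in range(5):
            fm = make_correlated_features(
                2000, np.array([[1.0, 0.5], [0.5, 1.0]]),
                [MarginalSpec("normal", (0, 1))] * 2, seed=200 + rep)
            res = normality_tests(fm, groups=[(0, 1)])
            hits += list(res["groups"].values())[0]["normal"]
        assert hits >= 4

    def test_non_normal_triplet_rejected(self):
        fm = make_correlated_features(
            3000, np.eye(3), [MarginalSpec("exponential", (1.0,))] * 3, seed=9)
        res = mardia_test(fm.values)
        assert not res["normal"]

    def test_oversized_group_rejected(self):
        fm = _fm(np.random.default_rng(1).normal(size=(50, 4)))
        with pytest.raises(ValueError, match="pairs or triplets"):
            normality_tests(fm, groups=[(0, 1, 2, 3)])


class TestCompareSets:
    def test_identity_comparison(self, rng):
        fm = _fm(rng.normal(size=(200, 3)))
        rep = compare_sets(fm, fm)
        assert all(v == 0.0 for v in rep.ks.values())
        assert rep.max_spearman_diff == 0.0

    def test_disjoint_supports(self, rng):
        a = _fm(rng.normal(size=(100, 2)))
        b = _fm(rng.normal(size=(100, 2)) + 100.0)
        rep = compare_sets(a, b)
        assert all(v == 1.0 for v in rep.ks.values())

    def test_simulated_correlation_agreement(self):
        R = np.array([[1, .6, .4], [.6, 1, .5], [.4, .5, 1]])
        fm = make_correlated_features(4000, R,
                                      [MarginalSpec("normal", (0, 1))] * 3, seed=31)
        model = fit_correlation_model(fm, "full")
        sim = simulate_features(model, 4000, np.random.default_rng(32))
        rep = compare_sets(fm, sim)
        assert rep.max_spearman_diff < 0.07


def metrics_oracle(pred, act):
    tp = sum(p == 1 and a == 1 for p, a in zip(pred, act))
    tn = sum(p == 0 and a == 0 for p, a in zip(pred, act))
    fp = sum(p == 1 and a == 0 for p, a in zip(pred, act))
    fn = sum(p == 0 and a == 1 for p, a in zip(pred, act))
    acc = (tp + tn) / len(pred)
    f = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / den ** 0.5 if den else 0.0
    return acc, f, mcc


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        assert classification_metrics(y, y) == (1.0, 1.0, 1.0)

    def test_inverted_balanced_gives_mcc_minus_one(self):
        y = np.array([0, 1] * 10)
        acc, f, mcc = classification_metrics(1 - y, y)
        assert mcc == pytest.approx(-1.0)

    def test_hand_confusion_oracle(self):
        # TP=8 FP=2 FN=2 TN=8
        act = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        acc, f, mcc = classification_metrics(pred, act)
        assert (acc, f, mcc) == (pytest.approx(0.8), pytest.approx(0.8),
                                 pytest.approx(0.6))

    def test_brute_force_on_random_vectors(self):
        gen = np.random.default_rng(77)
        for _ in range(1000):
            n = int(gen.integers(2, 40))
            pred = gen.integers(0, 2, size=n)
            act = gen.integers(0, 2, size=n)
            got = classification_metrics(pred, act)
            exp = metrics_oracle(pred, act)
            assert got == pytest.approx(exp)
            assert -1.0 <= got[2] <= 1.0 and 0.0 <= got[1] <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classification_metrics([0, 1], [0])


class TestClassifiers:
    @pytest.fixture(scope="class")
    def separated(self):
        gen = np.random.default_rng(55)
        a = gen.normal(0.0, 1.0, size=(200, 2))
        b = gen.normal(6.0, 1.0, size=(200, 2))
        X = np.vstack([a, b])
        y = np.array([0] * 200 + [1] * 200)
        idx = gen.permutation(400)
        return X[idx[:300]], y[idx[:300]], X[idx[300:]], y[idx[300:]]

    @pytest.mark.parametrize("kind", ["gaussian_naive_bayes", "pnn_gaussian",
                                      "pnn_exponential"])
    def test_separated_clusters_high_accuracy(self, separated, kind):
        Xtr, ytr, Xte, yte = separated
        model = train_classifier(Xtr, ytr, kind)
        acc, _, _ = classification_metrics(model.predict(Xte), yte)
        assert acc >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((10, 2)), np.zeros(10))

    def test_flat_kernel_collapses_to_majority(self, separated):
        Xtr, ytr, Xte, yte = separated
        ytr_imb = ytr.copy()
        ytr_imb[:5] = 1  # make class 1 the majority
        model = train_classifier(Xtr, ytr_imb, "pnn_gaussian", sigma=1e9)
        pred = model.predict(Xte)
        assert np.all(pred == np.bincount(ytr_imb).argmax())


class TestFeatureCombinationSearch:
    def test_subset_count(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        rows = feature_combination_search(_fm(X), _fm(X), y, y)
        assert len(rows) == 15

    def test_single_feature(self, rng):
        X = rng.normal(size=(40, 1))
        y = np.array([0, 1] * 20)
        rows = feature_combination_search(_fm(X), _fm(X), y, y)
        assert len(rows) == 1

    def test_informative_feature_dominates(self):
        hits = 0
        for rep in range(10):
            gen = np.random.default_rng(300 + rep)
            y = np.array([0] * 50 + [1] * 50)
            signal = y * 4.0 + gen.normal(size=100)
            X = np.column_stack([signal] + [gen.normal(size=100) for _ in range(3)])
            idx = gen.permutation(100)
            tr, te = idx[:70], idx[30:]
            rows = feature_combination_search(
                _fm(X[tr]), _fm(X[te]), y[tr], y[te])
            hits += "f1" in rows[0]["features"]
        assert hits >= 9
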