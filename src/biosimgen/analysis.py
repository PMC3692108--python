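"""Diagnostics and validation machinery.

Provides the tools used to judge simulation fidelity and downstream utility:
rank-correlation matrices, 1-D (Shapiro-Wilk) and 2-D/3-D (Mardia)
normality detection, original-versus-simulated comparison reports, and the
evaluation classifiers — Gaussian naive Bayes and probabilistic neural
networks (Parzen kernel classifiers) with Gaussian or exponential kernels —
scored by accuracy, F-score and the Matthews correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.naive_bayes import GaussianNB

from .densities import ks_distance
from .seqio import FeatureMatrix

CLASSIFIER_KINDS = ("gaussian_naive_bayes", "pnn_gaussian", "pnn_exponential")


def spearman_matrix(data: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Spearman rank-correlation matrix (average ranks on ties).

    Constant columns give NaN entries rather than a silent 0.
    """
    values = data.values if isinstance(data, FeatureMatrix) else np.asarray(data)
    n, p = values.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    if p == 1:
        return np.ones((1, 1))
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(values).statistic
    rho = np.atleast_2d(rho) if p > 2 else np.array(
        [[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return rho


def mardia_test(values: np.ndarray) -> dict:
    """Mardia's multivariate skewness and kurtosis tests.

    Skewness statistic n*b1/6 ~ chi-square with d(d+1)(d+2)/6 df; kurtosis
    b2 is asymptotically normal with mean d(d+2) and variance 8d(d+2)/n.
    """
    x = np.asarray(values, dtype=float)
    n, d = x.shape
    centered = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=0)
    inv = np.linalg.pinv(np.atleast_2d(cov))
    D = centered @ inv @ centered.T
    b1 = float((D ** 3).sum()) / n ** 2
    b2 = float(np.mean(np.diag(D) ** 2))
    df_skew = d * (d + 1) * (d + 2) / 6
    stat_skew = n * b1 / 6.0
    p_skew = float(stats.chi2.sf(stat_skew, df_skew))
    z_kurt = (b2 - d * (d + 2)) / np.sqrt(8.0 * d * (d + 2) / n)
    p_kurt = float(2.0 * stats.norm.sf(abs(z_kurt)))
    return {"b1": b1, "b2": b2, "p_skewness": p_skew, "p_kurtosis": p_kurt,
            "normal": bool(p_skew > 0.05 and p_kurt > 0.05)}


def normality_tests(data: FeatureMatrix,
                    groups: list[tuple[int, ...]] | None = None) -> dict:
    """1-D Shapiro-Wilk per feature plus Mardia tests per declared 2/3-group.

    A flag is True when every component test clears significance level 0.05.
    """
    if data.n < 20:
        raise ValueError("need n >= 20 for stable normality tests")
    per_feature = {}
    for j, name in enumerate(data.feature_names):
        col = data.values[:, j]
        # Shapiro-Wilk loses accuracy beyond 5000 points; subsample evenly
        if col.size > 5000:
            col = col[np.linspace(0, col.size - 1, 5000).astype(int)]
        stat, p = stats.shapiro(col)
        per_feature[name] = {"W": float(stat), "p": float(p),
                             "normal": bool(p > 0.05)}
    per_group = {}
    for g in groups or []:
        if len(g) not in (2, 3):
            raise ValueError("multivariate groups must be pairs or triplets")
        key = tuple(data.feature_names[j] for j in g)
        per_group[key] = mardia_test(data.values[:, list(g)])
    return {"features": per_feature, "groups": per_group}


@dataclass
class ComparisonReport:
    feature_names: list[str]
    ks: dict[str, float]
    spearman_original: np.ndarray
    spearman_simulated: np.ndarray
    spearman_abs_diff: np.ndarray
    histogram_bins: dict[str, np.ndarray]
    normality_original: dict | None = None

    @property
    def max_spearman_diff(self) -> float:
        off = ~np.eye(len(self.feature_names), dtype=bool)
        with np.errstate(invalid="ignore"):
            return float(np.nanmax(self.spearman_abs_diff[off])) if off.any() else 0.0

    def to_dict(self) -> dict:
        return {
            "ks": self.ks,
            "max_ks": max(self.ks.values()),
            "spearman_original": self.spearman_original.tolist(),
            "spearman_simulated": self.spearman_simulated.tolist(),
            "max_spearman_diff": self.max_spearman_diff,
        }


def compare_sets(original: FeatureMatrix, simulated: FeatureMatrix,
                 normality: bool = False) -> ComparisonReport:
    """Per-feature KS distances plus Spearman-matrix agreement."""
    if original.feature_names != simulated.feature_names:
        raise ValueError("feature name mismatch")
    ks = {name: ks_distance(original.values[:, j], simulated.values[:, j])
          for j, name in enumerate(original.feature_names)}
    rho_o = spearman_matrix(original)
    rho_s = spearman_matrix(simulated)
    bins = {}
    for j, name in enumerate(original.feature_names):
        pooled = np.concatenate([original.values[:, j], simulated.values[:, j]])
        bins[name] = np.histogram_bin_edges(pooled, bins="fd")
    norm = normality_tests(original) if normality and original.n >= 20 else None
    return ComparisonReport(list(original.feature_names), ks, rho_o, rho_s,
                            np.abs(rho_o - rho_s), bins, norm)


@dataclass
class ClassifierModel:
    """Binary classifier: Gaussian naive Bayes or a Parzen-kernel PNN."""

    kind: str
    priors: np.ndarray
    nb: GaussianNB | None = None
    train_points: dict[int, np.ndarray] = field(default_factory=dict)
    sigma: float = 1.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "gaussian_naive_bayes":
            return self.nb.predict(X).astype(int)
        scores = np.empty((X.shape[0], 2))
        for c in (0, 1):
            dist = cdist(X, self.train_points[c])
            if self.kind == "pnn_gaussian":
                k = np.exp(-dist ** 2 / (2.0 * self.sigma ** 2))
            else:
                k = np.exp(-dist / self.sigma)
            scores[:, c] = self.priors[c] * k.mean(axis=1)
        # flat-kernel ties fall back to the majority prior
        ties = scores[:, 0] == scores[:, 1]
        pred = scores.argmax(axis=1)
        pred[ties] = int(self.priors.argmax())
        return pred


def _default_sigma(X: np.ndarray) -> float:
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    s = float(nn[np.isfinite(nn)].mean())
    return s if s > 0 else 1.0


def train_classifier(train: FeatureMatrix | np.ndarray, labels,
                     kind: str = "gaussian_naive_bayes",
                     sigma: float | None = None) -> ClassifierModel:
    """Fit one of the three evaluation classifiers on binary-labelled data."""
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    if kind == "gaussian_naive_bayes":
        nb = GaussianNB(var_smoothing=1e-9)
        nb.fit(X, y)
        return ClassifierModel(kind, priors, nb=nb)
    if sigma is None:
        sigma = _default_sigma(X)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pts = {c: X[y == c] for c in (0, 1)}
    return ClassifierModel(kind, priors, train_points=pts, sigma=float(sigma))


def classification_metrics(predicted, actual) -> tuple[float, float, float]:
    """(accuracy, F-score, MCC) from the binary confusion matrix.

    MCC is reported as 0 when a confusion-matrix marginal is zero (the
    determinant formula is undefined there).
    """
    pred = np.asarray(predicted, dtype=int)
    act = np.asarray(actual, dtype=int)
    if pred.shape != act.shape:
        raise ValueError("length mismatch")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(act)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((pred == 1) & (act == 1)))
    tn = int(np.sum((pred == 0) & (act == 0)))
    fp = int(np.sum((pred == 1) & (act == 0)))
    fn = int(np.sum((pred == 0) & (act == 1)))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    f_denom = 2 * tp + fp + fn
    f_score = 2 * tp / f_denom if f_denom else 0.0
    m_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(m_denom)) if m_denom else 0.0
    return accuracy, f_score, float(mcc)


def feature_combination_search(train: FeatureMatrix, test: FeatureMatrix,
                               train_labels, test_labels,
                               kind: str = "gaussian_naive_bayes",
                               sigma: float | None = None) -> list[dict]:
    """Train/evaluate on every non-empty feature subset; rank by MCC then F."""
    p = train.p
    if p > 10:
        raise ValueError("exhaustive subset search limited to 10 features")
    rows = []
    for r in range(1, p + 1):
        for combo in combinations(range(p), r):
            Xtr = train.values[:, list(combo)]
            Xte = test.values[:, list(combo)]
            model = train_classifier(Xtr, train_labels, kind, sigma)
            acc, f, mcc = classification_metrics(model.predict(Xte), test_labels)
            rows.append({
                "features": tuple(train.feature_names[j] for j in combo),
                "accuracy": acc, "f_score": f, "mcc": mcc,
            })
    rows.sort(key=lambda r: (r["mcc"], r["f_score"]), reverse=True)
    return rows
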