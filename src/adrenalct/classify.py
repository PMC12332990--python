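"""Per-side incidentaloma classifiers and ROC statistics.

Rank statistics are implemented directly (not delegated to sklearn's
metrics): AUC as the Mann-Whitney concordance probability with half-credit
for ties, its variance and confidence interval from the placement-value
(midrank) covariance estimates, the Youden-optimal threshold by exhaustive
sweep, and paired/unpaired AUC comparison by the same placement machinery.
Candidate classifiers come from scikit-learn.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "ConfusionMatrix",
    "DelongResult",
    "roc_auc",
    "youden_threshold",
    "confusion_at_threshold",
    "delong_test",
    "fit_classifiers",
    "SUPPORTED_MODELS",
]


@dataclasses.dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: Tuple[float, float]
    variance: float


@dataclasses.dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(1, self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / max(1, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / max(1, self.tn + self.fp)


@dataclasses.dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    auc_difference: float
    variance: float
    z: float
    p_value: float
    degenerate: bool = False


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    return y


def _placements(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative); their
    means both equal the tie-corrected AUC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))  # midranks
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC (Mann-Whitney with half-credit ties); the 95% CI
    uses the placement-value variance with a normal approximation, clipped
    to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    if len(scores) != len(y):
        raise ValueError("scores and labels length mismatch")
    v10, v01 = _placements(scores, y)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    variance = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(variance)
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))

    # sweep over all distinct thresholds, rule "positive iff score >= t"
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    P = int(y.sum())
    N = len(y) - P
    tpr = np.array([(scores[y == 1] >= t).sum() / P for t in thresholds])
    fpr = np.array([(scores[y == 0] >= t).sum() / N for t in thresholds])
    return ROCResult(thresholds, tpr, fpr, auc, ci, float(variance))


def youden_threshold(roc: ROCResult) -> Tuple[float, float]:
    """Cut-off maximizing J = sensitivity + specificity - 1 over the swept
    thresholds; ties broken toward the lower threshold (higher
    sensitivity)."""
    if len(roc.thresholds) < 2:
        raise ValueError("need >= 2 candidate thresholds")
    j = roc.tpr - roc.fpr
    best_j = j.max()
    winners = np.flatnonzero(np.isclose(j, best_j, atol=1e-12))
    if len(winners) > 1:
        logger.info("Youden tie at J=%.4f; choosing the lowest threshold", best_j)
    idx = winners[np.argmin(roc.thresholds[winners])]
    return float(roc.thresholds[idx]), float(best_j)


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionMatrix:
    """Prediction positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        threshold=float(threshold),
    )


def delong_test(scores_a, scores_b, labels, paired: bool = True) -> DelongResult:
    """Compare two AUCs on the same label set.

    Paired: placement-value covariance of the AUC difference; unpaired:
    independent variances summed.  A zero-variance difference is reported
    as degenerate with p = 1.
    """
    y = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if paired and len(scores_a) != len(scores_b):
        raise ValueError("paired comparison requires equal-length score sets")
    v10a, v01a = _placements(scores_a, y)
    v10b, v01b = _placements(scores_b, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)

    def _var(v10, v01):
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        return s10 / m + s01 / n

    if paired:
        cov10 = np.cov(v10a, v10b, ddof=1)[0, 1] if m > 1 else 0.0
        cov01 = np.cov(v01a, v01b, ddof=1)[0, 1] if n > 1 else 0.0
        variance = _var(v10a, v01a) + _var(v10b, v01b) - 2.0 * (cov10 / m + cov01 / n)
    else:
        variance = _var(v10a, v01a) + _var(v10b, v01b)
    diff = auc_a - auc_b
    variance = max(float(variance), 0.0)
    if variance <= 1e-12:  # numerically zero: degenerate comparison
        return DelongResult(auc_a, auc_b, diff, 0.0, 0.0, 1.0, degenerate=True)
    z = diff / np.sqrt(variance)
    p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, diff, variance, float(z), p)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

SUPPORTED_MODELS = (
    "random_forest",
    "logistic_regression",
    "svm",
    "knn",
    "gradient_boosting",
    "naive_bayes",
)


def _make_model(name: str, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "logistic_regression":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=5000, random_state=seed)
        )
    if name == "svm":
        from sklearn.calibration import CalibratedClassifierCV

        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(random_state=seed), cv=3, ensemble=False),
        )
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(
        f"unknown model {name!r}; supported: {', '.join(SUPPORTED_MODELS)}"
    )


@dataclasses.dataclass
class FittedCandidate:
    name: str
    estimator: object
    valid_scores: np.ndarray
    roc: ROCResult


@dataclasses.dataclass
class ClassifierComparison:
    candidates: Dict[str, FittedCandidate]
    selected: str

    @property
    def best(self) -> FittedCandidate:
        return self.candidates[self.selected]


def fit_classifiers(train_X, train_y, valid_X, valid_y,
                    model_set: Sequence[str] = SUPPORTED_MODELS,
                    seed: int = 0) -> ClassifierComparison:
    """Fit each named model on the training split, score the validation
    split, and flag the highest-validation-AUC model as selected (ties go to
    the first name in ``model_set``)."""
    train_y = _check_binary(train_y)
    _check_binary(valid_y)
    train_X = np.asarray(train_X, dtype=float)
    valid_X = np.asarray(valid_X, dtype=float)
    candidates: Dict[str, FittedCandidate] = {}
    best_name, best_auc = None, -np.inf
    for name in model_set:
        est = _make_model(name, seed)
        est.fit(train_X, train_y)
        scores = est.predict_proba(valid_X)[:, 1]
        roc = roc_auc(scores, valid_y)
        candidates[name] = FittedCandidate(name, est, scores, roc)
        if roc.auc > best_auc:
            best_name, best_auc = name, roc.auc
    return ClassifierComparison(candidates, best_name)


def summarize_operating_point(scores, labels, threshold=None) -> pd.Series:
    """Acc / AUC / CI / Sens / Spec / threshold summary row; threshold
    defaults to the Youden optimum."""
    roc = roc_auc(scores, labels)
    if threshold is None:
        threshold, _ = youden_threshold(roc)
    cm = confusion_at_threshold(scores, labels, threshold)
    return pd.Series(
        {
            "acc_pct": cm.accuracy * 100.0,
            "auc_pct": roc.auc * 100.0,
            "auc_ci_low_pct": roc.ci95[0] * 100.0,
            "auc_ci_high_pct": roc.ci95[1] * 100.0,
            "sens_pct": cm.sensitivity * 100.0,
            "spec_pct": cm.specificity * 100.0,
            "threshold": threshold,
        }
    )
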