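"""Binary degradation-activity classification and model validation.

Descriptor tables are labeled active/inactive at a degradation cutoff and
modeled with five standard classifiers (random forest, single randomized
tree, Gaussian naive Bayes, 5-nearest-neighbours, linear-kernel SVM). Model
quality is assessed by 10-fold cross-validation with pooled out-of-fold
confusion counts, by external validation on a held-out test partition, and
by Y-randomization (retraining on permuted labels to estimate chance-level
performance). Metrics are sensitivity (TPR), specificity (TNR), the Matthews
correlation coefficient (MCC, with an MCC above 0.4 conventionally marking a
robust model) and the rank-based ROC area. Attribute relevance is ranked
with information gain, Pearson correlation, OneR and correlation-based
feature-subset selection (CFS).

Classifier fitting is delegated to scikit-learn; folds, metrics,
Y-randomization and the attribute evaluators are implemented here so they
are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import DegradationRecord, binarize_activity

ALGORITHMS = ("RF", "RT", "NB", "KNN5", "SVM_linear")
EVALUATORS = ("InfoGain", "PearsonCorrelation", "OneR", "CFS")
ROBUST_MCC = 0.4


def make_classifier(algorithm: str, seed: int = 0):
    """A fresh scikit-learn estimator for one of the five algorithms."""
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algorithm == "RT":
        return DecisionTreeClassifier(splitter="random", random_state=seed)
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "KNN5":
        return KNeighborsClassifier(n_neighbors=5)
    if algorithm == "SVM_linear":
        return SVC(kernel="linear", C=1.0)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


# ---------------------------------------------------------------------------
# Tables and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTable:
    """Descriptor rows with binary activity labels for one data subset."""

    ids: tuple[str, ...]
    X: pd.DataFrame            # one row per id, descriptor columns
    y: np.ndarray              # boolean labels, aligned with ids
    subset: str = "all"        # VHL | CRBN | all

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.X) or len(self.ids) != len(self.y):
            raise ValueError("ids, X and y must be aligned")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")


def build_feature_table(
    records: Sequence[DegradationRecord],
    descriptors: pd.DataFrame,
    threshold: float = 75.0,
    subset: str = "all",
    concentration: str = "low",
) -> FeatureTable:
    """Join records with their descriptor rows and binarize activity."""
    keep = [r for r in records if subset == "all" or r.e3_class == subset]
    ids = tuple(r.id for r in keep)
    values = (
        [r.deg_low for r in keep] if concentration == "low" else [r.deg_high for r in keep]
    )
    y = np.array([binarize_activity(v, threshold).active for v in values], dtype=bool)
    return FeatureTable(ids=ids, X=descriptors.loc[list(ids)].copy(), y=y, subset=subset)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class ModelReport:
    algorithm: str
    phase: str  # cv_training | external_test
    TPR: float
    TNR: float
    MCC: float
    roc_area: float
    seed: int
    subset: str = "all"


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and MCC from a confusion table.

    MCC is defined as 0 when any marginal is empty (all predictions or all
    labels in one class).
    """
    if c.TP + c.FN < 1 or c.TN + c.FP < 1:
        raise ValueError("TPR/TNR need at least one positive and one negative label")
    tpr = c.TP / (c.TP + c.FN)
    tnr = c.TN / (c.TN + c.FP)
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    return float(tpr), float(tnr), float(mcc)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) ROC area; tied scores contribute 1/2."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _score(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        positive = list(estimator.classes_).index(True) if True in estimator.classes_ else None
        if positive is None:
            return np.zeros(len(X))
        return proba[:, positive]
    return estimator.decision_function(X)


# ---------------------------------------------------------------------------
# Cross-validation and external testing
# ---------------------------------------------------------------------------

def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Plain random fold ids (0..k-1); fold sizes differ by at most one."""
    if n < k:
        raise ValueError("need n >= k samples for k folds")
    sizes = [n // k + (1 if fold < n % k else 0) for fold in range(k)]
    base = np.concatenate([np.full(size, fold) for fold, size in enumerate(sizes)])
    return base[np.random.default_rng(seed).permutation(n)]


def crossvalidate_classifier(
    table: FeatureTable, algorithm: str, k: int = 10, seed: int = 0
) -> ModelReport:
    """k-fold CV with pooled out-of-fold predictions.

    Folds are unstratified uniform random, deterministic given the seed; the
    pooled confusion table and pooled out-of-fold scores yield the metrics.
    """
    y = table.y
    if y.all() or (~y).all():
        raise ValueError("cross-validation needs both classes in the table")
    X = table.X.to_numpy(dtype=float)
    folds = assign_folds(len(y), k, seed)
    pred = np.zeros(len(y), dtype=bool)
    scores = np.zeros(len(y), dtype=float)
    for fold in range(k):
        mask = folds == fold
        est = make_classifier(algorithm, seed=seed + fold)
        est.fit(X[~mask], y[~mask])
        pred[mask] = est.predict(X[mask])
        scores[mask] = _score(est, X[mask])
    counts = ConfusionCounts(
        TP=int((pred & y).sum()),
        FP=int((pred & ~y).sum()),
        TN=int((~pred & ~y).sum()),
        FN=int((~pred & y).sum()),
    )
    tpr, tnr, mcc = confusion_metrics(counts)
    return ModelReport(
        algorithm=algorithm,
        phase="cv_training",
        TPR=tpr,
        TNR=tnr,
        MCC=mcc,
        roc_area=roc_auc(scores, y),
        seed=seed,
        subset=table.subset,
    )


@dataclass(frozen=True)
class FittedModel:
    algorithm: str
    estimator: object
    train_ids: frozenset[str]
    seed: int
    subset: str = "all"


def train_classifier(table: FeatureTable, algorithm: str, seed: int = 0) -> FittedModel:
    est = make_classifier(algorithm, seed=seed)
    est.fit(table.X.to_numpy(dtype=float), table.y)
    return FittedModel(
        algorithm=algorithm,
        estimator=est,
        train_ids=frozenset(table.ids),
        seed=seed,
        subset=table.subset,
    )


def evaluate_on_test(model: FittedModel, test_table: FeatureTable) -> ModelReport:
    """External validation on an untouched test partition."""
    overlap = model.train_ids & set(test_table.ids)
    if overlap:
        raise ValueError(f"train/test id overlap: {sorted(overlap)[:5]}")
    X = test_table.X.to_numpy(dtype=float)
    y = test_table.y
    pred = np.asarray(model.estimator.predict(X), dtype=bool)
    counts = ConfusionCounts(
        TP=int((pred & y).sum()),
        FP=int((pred & ~y).sum()),
        TN=int((~pred & ~y).sum()),
        FN=int((~pred & y).sum()),
    )
    tpr, tnr, mcc = confusion_metrics(counts)
    return ModelReport(
        algorithm=model.algorithm,
        phase="external_test",
        TPR=tpr,
        TNR=tnr,
        MCC=mcc,
        roc_area=roc_auc(_score(model.estimator, X), y),
        seed=model.seed,
        subset=test_table.subset,
    )


# ---------------------------------------------------------------------------
# Y-randomization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YRandomizationResult:
    mccs: tuple[float, ...]
    mean_mcc: float
    algorithm: str
    n_perm: int
    seed: int


def y_randomization(
    table: FeatureTable,
    algorithm: str,
    n_perm: int = 20,
    seed: int = 0,
    k: int = 10,
) -> YRandomizationResult:
    """Chance-level MCC distribution from label-permuted refits.

    Labels are permuted (class counts preserved) and the full CV repeated
    per permutation; an informative model should sit far above this null.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    rng = np.random.default_rng(seed)
    mccs = []
    for p in range(n_perm):
        perm = rng.permutation(len(table.y))
        shuffled = FeatureTable(
            ids=table.ids, X=table.X, y=table.y[perm], subset=table.subset
        )
        report = crossvalidate_classifier(
            shuffled, algorithm, k=k, seed=int(rng.integers(0, 2**31 - 1))
        )
        mccs.append(report.MCC)
    return YRandomizationResult(
        mccs=tuple(mccs),
        mean_mcc=float(np.mean(mccs)),
        algorithm=algorithm,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Attribute evaluators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeRanking:
    evaluator: str
    ranking: tuple[tuple[str, float], ...]  # (attribute, score), descending
    selected: tuple[str, ...] = ()          # CFS subset (empty otherwise)
    merit: float = float("nan")             # CFS subset merit


def _entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))


def _best_single_cut(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(information gain, cut) of the best binary split of attribute x."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    h_class = _entropy(ys)
    best_gain, best_cut = 0.0, float("nan")
    uniques = np.unique(xs)
    if len(uniques) < 2:
        return 0.0, best_cut
    cuts = (uniques[:-1] + uniques[1:]) / 2
    n = len(ys)
    for cut in cuts:
        left = ys[xs <= cut]
        right = ys[xs > cut]
        h_cond = (len(left) / n) * _entropy(left) + (len(right) / n) * _entropy(right)
        gain = h_class - h_cond
        if gain > best_gain:
            best_gain, best_cut = float(gain), float(cut)
    return best_gain, best_cut


def _oner_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Accuracy of the best one-attribute single-cut rule."""
    uniques = np.unique(x)
    if len(uniques) < 2:
        return float(max(y.mean(), 1 - y.mean()))
    best = 0.0
    for cut in (uniques[:-1] + uniques[1:]) / 2:
        for orientation in (x <= cut, x > cut):
            left_major = y[orientation].mean() >= 0.5 if orientation.any() else False
            pred = np.where(orientation, left_major, not left_major)
            best = max(best, float((pred == y).mean()))
    return best


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y.astype(float))[0, 1]))


def _cfs(X: pd.DataFrame, y: np.ndarray) -> tuple[tuple[str, ...], float, list[tuple[str, float]]]:
    """Greedy forward correlation-based feature selection.

    merit(S) = k * mean|r(feature, class)| / sqrt(k + k(k-1) * mean|r(fi, fj)|)
    """
    names = list(X.columns)
    r_cf = {name: _abs_pearson(X[name].to_numpy(float), y) for name in names}
    r_ff = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            key = tuple(sorted((a, b)))
            r_ff[key] = _abs_pearson(X[a].to_numpy(float), X[b].to_numpy(float))

    def merit(subset: list[str]) -> float:
        k = len(subset)
        if k == 0:
            return 0.0
        mean_cf = np.mean([r_cf[name] for name in subset])
        if k == 1:
            return float(mean_cf)
        pairs = [
            r_ff[tuple(sorted((a, b)))] for i, a in enumerate(subset) for b in subset[i + 1 :]
        ]
        mean_ff = np.mean(pairs)
        return float(k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff))

    selected: list[str] = []
    trace: list[tuple[str, float]] = []
    current = 0.0
    while True:
        candidates = [
            (merit(selected + [name]), name)
            for name in names
            if name not in selected
        ]
        if not candidates:
            break
        best_merit, best_name = max(candidates, key=lambda mn: (mn[0], mn[1]))
        if best_merit <= current:
            break
        selected.append(best_name)
        trace.append((best_name, best_merit))
        current = best_merit
    return tuple(selected), current, trace


def rank_attributes(table: FeatureTable, evaluator: str) -> AttributeRanking:
    """Score and rank attributes against the binary class.

    InfoGain and OneR discretize each continuous attribute with the single
    binary cut maximizing information gain (resp. rule accuracy); the
    Pearson evaluator ranks by absolute correlation with the class; CFS
    returns the greedy forward-selected subset with its merit.
    """
    if evaluator not in EVALUATORS:
        raise ValueError(f"unknown evaluator {evaluator!r}; expected one of {EVALUATORS}")
    y = table.y.astype(float)
    names = list(table.X.columns)
    if evaluator == "CFS":
        selected, merit, trace = _cfs(table.X, table.y)
        ranking = tuple(sorted(trace, key=lambda ns: -ns[1]))
        return AttributeRanking(
            evaluator=evaluator, ranking=ranking, selected=selected, merit=merit
        )
    scores = []
    for name in names:
        x = table.X[name].to_numpy(dtype=float)
        if evaluator == "InfoGain":
            score, _ = _best_single_cut(x, table.y)
        elif evaluator == "PearsonCorrelation":
            score = _abs_pearson(x, y)
        else:  # OneR
            score = _oner_accuracy(x, table.y)
        scores.append((name, float(score)))
    scores.sort(key=lambda ns: (-ns[1], ns[0]))
    return AttributeRanking(evaluator=evaluator, ranking=tuple(scores))
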