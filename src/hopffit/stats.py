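"""Group statistics and classification metrics downstream of fitting.

Once per-subject bifurcation vectors are fitted, group comparisons run a
per-region Welch t-test with Benjamini-Hochberg FDR correction and Cohen's d
effect sizes (the significance rule used throughout: p_fdr < 0.05 together
with |d| > 0.25).  Confusion-matrix metrics (accuracy, precision, recall,
F1) and a thin stratified-CV SVM wrapper support using the fitted parameters
as classification features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError, InvalidConfigurationError, InvalidInputError

__all__ = [
    "GroupComparison",
    "ConfusionCounts",
    "cohens_d",
    "ttest_by_region",
    "bh_fdr",
    "classification_metrics",
    "classify_subjects",
]


@dataclass
class GroupComparison:
    """Per-region Welch t, raw and FDR-adjusted p, and Cohen's d."""

    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    d: np.ndarray
    n_a: int
    n_b: int

    def significant(self, alpha: float = 0.05, d_threshold: float = 0.25) -> np.ndarray:
        """Mask of regions with p_fdr < alpha and |d| > d_threshold."""
        return (self.p_fdr < alpha) & (np.abs(self.d) > d_threshold)


@dataclass
class ConfusionCounts:
    """Binary-classification confusion-matrix counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise InvalidInputError("confusion counts must not all be zero")


def cohens_d(x, y) -> float:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD.

    Pooled SD is the classical estimator
    sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidInputError("cohens_d requires at least 2 observations per group")
    n1, n2 = x.size, y.size
    s_pooled = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise DegenerateInputError("cohens_d undefined: zero pooled standard deviation")
    return float((x.mean() - y.mean()) / s_pooled)


def ttest_by_region(A: np.ndarray, B: np.ndarray, q: float = 0.05) -> GroupComparison:
    """Per-region two-sided Welch t-test between two subjects x N matrices.

    Regions where both groups have zero variance get t = 0, p = 1 and d = 0
    (flagged as undefined rather than erroring the whole comparison).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise InvalidInputError("groups must have the same number of regions")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise InvalidInputError("each group needs at least 2 subjects")
    res = spstats.ttest_ind(A, B, axis=0, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    d = np.empty(A.shape[1])
    for j in range(A.shape[1]):
        try:
            d[j] = cohens_d(A[:, j], B[:, j])
        except DegenerateInputError:
            d[j] = 0.0
    p_fdr, _ = bh_fdr(p, q)
    return GroupComparison(t=t, p=p, p_fdr=p_fdr, d=d, n_a=A.shape[0], n_b=B.shape[0])


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted p-values, boolean rejection mask at level q).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def classification_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    A metric whose denominator is zero is returned as NaN (flagged
    undefined) without affecting the others.
    """
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": ratio(tp, tp + fp),
        "recall": ratio(tp, tp + fn),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


def classify_subjects(
    features: np.ndarray,
    labels: np.ndarray,
    kernel: str = "linear",
    seed: int = 0,
    n_folds: int = 5,
    oversample: bool = True,
) -> dict[str, tuple[float, float]]:
    """Thin stratified-CV SVM wrapper over the fitted parameter features.

    Features are z-scored on the training folds; imbalanced training folds
    are rebalanced by with-replacement duplication of minority rows.  The
    RBF kernel grid-searches C in {1, 10, 100, 1000} and gamma in
    {1e-4, 1e-3, 1e-2, 1e-1} with an inner stratified CV; the linear kernel
    uses C = 1.  Returns mean and SD of accuracy / precision / recall / F1
    across the outer folds.
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError("features and labels must have matching length")
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidConfigurationError("classify_subjects supports exactly 2 classes")
    if X.shape[0] < 2 * n_folds:
        raise InvalidConfigurationError("too few subjects for the requested folds")

    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    fold_metrics: dict[str, list[float]] = {
        "accuracy": [], "precision": [], "recall": [], "f1": []
    }
    positive = classes[1]
    for train_idx, test_idx in outer.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if oversample:
            counts = {c: int((y_tr == c).sum()) for c in classes}
            minority = min(counts, key=counts.get)
            deficit = max(counts.values()) - counts[minority]
            if deficit > 0:
                pool = np.flatnonzero(y_tr == minority)
                extra = rng.choice(pool, size=deficit, replace=True)
                X_tr = np.vstack([X_tr, X_tr[extra]])
                y_tr = np.concatenate([y_tr, y_tr[extra]])
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        if kernel == "rbf":
            grid = {"C": [1, 10, 100, 1000], "gamma": [1e-4, 1e-3, 1e-2, 1e-1]}
            inner = StratifiedKFold(n_splits=min(n_folds, 3), shuffle=True, random_state=seed)
            clf = GridSearchCV(SVC(kernel="rbf"), grid, cv=inner)
        elif kernel == "linear":
            clf = SVC(kernel="linear", C=1)
        else:
            raise InvalidConfigurationError(f"unknown kernel {kernel!r}")
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        cc = ConfusionCounts(
            tp=int(((pred == positive) & (y_te == positive)).sum()),
            tn=int(((pred != positive) & (y_te != positive)).sum()),
            fp=int(((pred == positive) & (y_te != positive)).sum()),
            fn=int(((pred != positive) & (y_te == positive)).sum()),
        )
        for k, v in classification_metrics(cc).items():
            fold_metrics[k].append(v)
    return {
        k: (float(np.nanmean(v)), float(np.nanstd(v))) for k, v in fold_metrics.items()
    }
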