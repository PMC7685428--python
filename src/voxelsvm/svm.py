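"""Linear soft-margin SVM: solver, C selection, metrics, performance permutation.

The classifier follows the study's label convention — patient = -1,
control = +1 — and solves the standard L1-loss soft-margin dual

    min_a  1/2 a' Q a - 1'a   s.t. 0 <= a_i <= C,  y'a = 0,   Q = yy' o K

with a maximal-violating-pair SMO working-set scheme (the classical
sequential-minimal-optimization approach for this dual). The Gram matrix is
precomputed: cohorts here have ~100 subjects and many voxels, so the n x n
kernel is the cheap object. Decision rule d(x) = w.x + b with
w = sum_i a_i y_i x_i; ties d = 0 predict patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LinearSVM",
    "PerformanceReport",
    "train_linear_svm",
    "select_C",
    "evaluate",
    "permutation_test_performance",
    "permutation_test_cv_accuracy",
    "default_c_grid",
]

PATIENT, CONTROL = -1, 1


def default_c_grid() -> np.ndarray:
    """log2-spaced C grid 2^-10 ... 2^10 (21 points)."""
    return 2.0 ** np.arange(-10, 11, dtype=np.float64)


class LinearSVM(BaseEstimator, ClassifierMixin):
    """Linear soft-margin SVM trained by SMO on the precomputed-Gram dual.

    Parameters
    ----------
    C : float
        Soft-margin regularization parameter (> 0).
    tol : float
        KKT violation tolerance for the stopping rule (max violating pair).
    max_iter : int
        Cap on pairwise working-set updates.

    Attributes
    ----------
    coef_ : ndarray, shape (1, p)
        Primal weight vector w.
    intercept_ : ndarray, shape (1,)
        Bias b.
    alpha_ : ndarray, shape (n,)
        Dual variables.
    support_ : ndarray
        Indices with alpha > 0.
    dual_objective_ : float
        Value of sum(a) - 1/2 a'Qa at the solution.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-6, max_iter: int = 200000):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self._validate(X, y)
        K = X @ X.T
        alpha, b, n_iter = _smo_solve(K, y, self.C, self.tol, self.max_iter)
        self.alpha_ = alpha
        self.dual_coef_ = alpha * y
        self.coef_ = (self.dual_coef_ @ X).reshape(1, -1)
        self.intercept_ = np.array([b])
        self.support_ = np.flatnonzero(alpha > 1e-12)
        self.n_iter_ = n_iter
        self.classes_ = np.array([PATIENT, CONTROL], dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        self.dual_objective_ = float(alpha.sum() - 0.5 * self.dual_coef_ @ K @ self.dual_coef_)
        return self

    def fit_gram(self, K: np.ndarray, y: np.ndarray):
        """Fit from a precomputed Gram matrix; coef_ is left unset."""
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present in y")
        alpha, b, n_iter = _smo_solve(np.asarray(K, float), y, self.C, self.tol, self.max_iter)
        self.alpha_ = alpha
        self.dual_coef_ = alpha * y
        self.intercept_ = np.array([b])
        self.n_iter_ = n_iter
        self.classes_ = np.array([PATIENT, CONTROL], dtype=np.float64)
        return self

    def _validate(self, X, y) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        labels = set(np.unique(y))
        if not labels.issubset({-1.0, 1.0}):
            raise ValueError(f"labels must be in {{-1, +1}}, got {sorted(labels)}")
        if len(labels) < 2:
            raise ValueError("need both classes present in y")

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # ties (d == 0) go to the patient class
        return np.where(d > 0, CONTROL, PATIENT).astype(np.float64)


def _smo_solve(
    K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int]:
    """Maximal-violating-pair SMO on the precomputed Gram matrix."""
    n = len(y)
    alpha = np.zeros(n)
    f = np.zeros(n)  # f_k = sum_l alpha_l y_l K_kl
    it = 0
    while it < max_iter:
        it += 1
        E = f - y
        up = ((alpha < C - 1e-12) & (y > 0)) | ((alpha > 1e-12) & (y < 0))
        low = ((alpha < C - 1e-12) & (y < 0)) | ((alpha > 1e-12) & (y > 0))
        if not up.any() or not low.any():
            break
        neg_e = -E
        i = np.flatnonzero(up)[np.argmax(neg_e[up])]
        j = np.flatnonzero(low)[np.argmin(neg_e[low])]
        m, M = neg_e[i], neg_e[j]
        if m - M <= tol:
            break
        yi, yj = y[i], y[j]
        ai_old, aj_old = alpha[i], alpha[j]
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= 1e-14:
            eta = 1e-14
        aj_new = aj_old + yj * (E[i] - E[j]) / eta
        if yi != yj:
            L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
        else:
            L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
        aj_new = min(max(aj_new, L), H)
        ai_new = ai_old + yi * yj * (aj_old - aj_new)
        if abs(aj_new - aj_old) < 1e-15:
            break
        alpha[i], alpha[j] = ai_new, aj_new
        f += (ai_new - ai_old) * yi * K[i] + (aj_new - aj_old) * yj * K[j]

    # bias from free support vectors, midpoint of the violating bounds otherwise
    E = f - y
    free = (alpha > 1e-9) & (alpha < C - 1e-9)
    if free.any():
        b = float(np.mean(-E[free]))
    else:
        up = ((alpha < C - 1e-12) & (y > 0)) | ((alpha > 1e-12) & (y < 0))
        low = ((alpha < C - 1e-12) & (y < 0)) | ((alpha > 1e-12) & (y > 0))
        neg_e = -E
        hi = neg_e[up].max() if up.any() else 0.0
        lo = neg_e[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b, it


def train_linear_svm(X, y, C: float = 1.0, tol: float = 1e-6) -> LinearSVM:
    """Functional wrapper: fit a :class:`LinearSVM` and return it."""
    return LinearSVM(C=C, tol=tol).fit(X, y)


def select_C(
    X,
    y,
    grid=None,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Pick C by stratified k-fold cross-validated accuracy.

    Accuracy per C is pooled over held-out folds. Ties break toward the
    smaller C (stronger regularization). Returns (C_best, accuracy-per-C
    aligned with the ascending grid).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    grid = np.sort(np.asarray(default_c_grid() if grid is None else grid, dtype=np.float64))
    if grid.size == 0:
        raise ValueError("C grid must be non-empty")
    counts = [int((y == c).sum()) for c in (-1, 1)]
    if k > min(counts):
        raise ValueError(
            f"k={k} folds exceed the smaller class size {min(counts)}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    acc = np.zeros(len(grid))
    for ci, C in enumerate(grid):
        correct = 0
        for train_idx, test_idx in folds:
            model = LinearSVM(C=C).fit(X[train_idx], y[train_idx])
            correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
        acc[ci] = correct / len(y)
    best = int(np.argmax(acc))  # argmax returns the first (smallest C) on ties
    return float(grid[best]), acc


@dataclass
class PerformanceReport:
    """Confusion counts and derived metrics with patient as positive class.

    Rates are fractions in [0, 1]; undefined ratios (zero denominator) are
    NaN, never 0. ``auc`` orients the decision value so that higher risk
    implies patient.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    auc: float = np.nan
    p_accuracy: float | None = None
    p_auc: float | None = None

    @property
    def n_patients(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.n_patients + self.n_controls)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "n_patients": self.n_patients, "n_controls": self.n_controls,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "auc": self.auc, "p_accuracy": self.p_accuracy, "p_auc": self.p_auc,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def confusion_from_predictions(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == PATIENT) & (y_pred == PATIENT)).sum())
    fn = int(((y_true == PATIENT) & (y_pred == CONTROL)).sum())
    tn = int(((y_true == CONTROL) & (y_pred == CONTROL)).sum())
    fp = int(((y_true == CONTROL) & (y_pred == PATIENT)).sum())
    return tp, fn, tn, fp


def auc_from_decision(y_true, decision) -> float:
    """Rank-based AUC: P(risk_patient > risk_control) + half ties.

    Risk = -decision value, since patients carry label -1 (lower decision
    values mean higher disease risk).
    """
    y_true = np.asarray(y_true)
    risk = -np.asarray(decision, dtype=np.float64)
    pos = risk[y_true == PATIENT]
    neg = risk[y_true == CONTROL]
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    ranks = rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


def evaluate(model: LinearSVM, X_test, y_test) -> PerformanceReport:
    """Score a fitted model on held-out subjects."""
    if hasattr(model, "n_features_in_") and np.shape(X_test)[1] != model.n_features_in_:
        raise ValueError(
            f"test features have {np.shape(X_test)[1]} voxels but the model was "
            f"trained on {model.n_features_in_}"
        )
    d = model.decision_function(X_test)
    pred = np.where(d > 0, CONTROL, PATIENT)
    tp, fn, tn, fp = confusion_from_predictions(y_test, pred)
    return PerformanceReport(tp=tp, fn=fn, tn=tn, fp=fp, auc=auc_from_decision(y_test, d))


def _permutation_iter(rng: np.random.Generator, n: int, B: int, permutations):
    if permutations is not None:
        for perm in permutations:
            yield np.asarray(perm, dtype=int)
    else:
        for _ in range(B):
            yield rng.permutation(n)


def permutation_test_performance(
    X_train,
    y_train,
    X_test,
    y_test,
    C: float,
    B: int = 5000,
    seed: int = 0,
    permutations=None,
) -> PerformanceReport:
    """Permutation p-values for cross-site accuracy and AUC.

    Each iteration permutes the TRAINING labels, retrains at the fixed C of
    the unpermuted fit, and scores the unpermuted test set. p-values are
    count-based with a 1/B floor: p = max(#{null >= observed}, 1)/B, so the
    smallest reportable p at B = 5000 is 2e-4. Pass ``permutations`` (an
    iterable of index arrays applied to y_train) to enumerate an explicit
    null instead of sampling; B is then its length.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y_train = np.asarray(y_train, dtype=np.float64)
    rng = np.random.default_rng(seed)
    observed = evaluate(LinearSVM(C=C).fit(X_train, y_train), X_test, y_test)
    null_acc, null_auc = [], []
    for perm in _permutation_iter(rng, len(y_train), B, permutations):
        y_perm = y_train[perm]
        if len(np.unique(y_perm)) < 2:  # degenerate permutation on tiny toys
            continue
        rep = evaluate(LinearSVM(C=C).fit(X_train, y_perm), X_test, y_test)
        null_acc.append(rep.accuracy)
        null_auc.append(rep.auc)
    B_eff = len(null_acc)
    observed.p_accuracy = max(int(np.sum(np.asarray(null_acc) >= observed.accuracy)), 1) / B_eff
    observed.p_auc = max(int(np.sum(np.asarray(null_auc) >= observed.auc)), 1) / B_eff
    return observed


def cv_accuracy(X, y, C: float, k: int = 10, seed: int = 0) -> float:
    """Accuracy pooled over held-out folds of stratified k-fold CV at fixed C."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        model = LinearSVM(C=C).fit(X[train_idx], y[train_idx])
        correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def permutation_test_cv_accuracy(
    X, y, C: float, k: int = 10, B: int = 5000, seed: int = 0
) -> tuple[float, float]:
    """(observed CV accuracy, permutation p): labels permuted before the CV loop."""
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    observed = cv_accuracy(X, y, C, k=k, seed=seed)
    null = []
    for _ in range(B):
        y_perm = y[rng.permutation(len(y))]
        null.append(cv_accuracy(X, y_perm, C, k=k, seed=seed))
    p = max(int(np.sum(np.asarray(null) >= observed)), 1) / B
    return observed, p
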