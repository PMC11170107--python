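"""Repeated-split LASSO selection, stepwise reduction and confusion metrics.

The response (compound group) is coded numerically and fit with an
L1-penalized linear model; over repeated stratified train/test splits the
nonzero-coefficient parameters are counted, yielding a selection frequency
per parameter and a balanced-error-rate (BER) estimate per repeat.  For
three or more groups a one-vs-rest scheme is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io_formats import ValidationError

__all__ = [
    "ConfusionMetrics",
    "LabeledFeatureTable",
    "SelectionReport",
    "classification_metrics",
    "lasso_select",
    "stepwise_reduce",
    "multiclass_ber",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    ber: float
    ppv: float
    npv: float
    kappa: float


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Binary confusion-matrix metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    balanced accuracy = (sensitivity + specificity)/2;
    BER = 0.5*(FP/(TN+FP) + FN/(FN+TP)); PPV = TP/(TP+FP); NPV = TN/(TN+FN);
    kappa = 2*(TP*TN - FN*FP) / ((TP+FP)*(FP+TN) + (TP+FN)*(FN+TN)).
    PPV/NPV are NaN when their denominators are 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValidationError(f"{name} must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValidationError("all-zero confusion matrix: metrics undefined")
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError(
            "ratio metrics require tp+fn > 0 and tn+fp > 0"
        )
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    bal = (sens + spec) / 2.0
    ber = 0.5 * (fp / (tn + fp) + fn / (fn + tp))
    ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
    npv = tn / (tn + fn) if tn + fn > 0 else math.nan
    denom = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    kappa = 2.0 * (tp * tn - fn * fp) / denom if denom else math.nan
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, bal, ber, ppv, npv, kappa)


# ---------------------------------------------------------------------------
# labeled tables
# ---------------------------------------------------------------------------


@dataclass
class LabeledFeatureTable:
    """Feature matrix (wells/conditions x parameter panel) with class labels."""

    X: pd.DataFrame
    y: np.ndarray
    unpenalized: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != self.y.size:
            raise ValidationError("X and y length mismatch")
        if np.unique(self.y).size < 2:
            raise ValidationError("at least 2 classes required")

    def imputed(self) -> "LabeledFeatureTable":
        """Median-impute missing entries; drop all-missing columns."""
        X = self.X.copy()
        X = X.dropna(axis=1, how="all")
        X = X.fillna(X.median(numeric_only=True))
        return LabeledFeatureTable(X, self.y, self.unpenalized)


@dataclass
class SelectionReport:
    frequencies: pd.Series  # parameter -> selection frequency in [0, 1]
    test_ber: np.ndarray  # one BER per repeat
    threshold: float
    retained: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.retained = sorted(
            self.frequencies[self.frequencies >= self.threshold].index
        )


def multiclass_ber(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class error rates (1 - recall); binary case matches the
    printed two-class BER formula."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    errs = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        errs.append(np.mean(y_pred[mask] != cls))
    return float(np.mean(errs))


def _fit_ovr_lasso(
    X: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    cv_folds: int,
    rng_seed: int,
    unpen_idx: np.ndarray,
):
    """One-vs-rest L1 linear fits with CV-chosen penalty.

    Features are standardized inside the fit; returns (selected-feature mask,
    per-class coefficient matrix, intercepts, standardization constants).
    Columns in ``unpen_idx`` never count as droppable: they are always
    treated as selected.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_classes = classes.size
    coefs = np.zeros((n_classes, X.shape[1]))
    intercepts = np.zeros(n_classes)
    folds = min(cv_folds, max(2, np.bincount(np.searchsorted(classes, y)).min()))
    targets = [(y == c).astype(float) for c in classes]
    if n_classes == 2:
        targets = targets[1:]  # one fit suffices for two classes
    for i, t in enumerate(targets):
        model = LassoCV(cv=folds, random_state=rng_seed, alphas=40)
        model.fit(Z, t)
        row = 1 if n_classes == 2 else i
        coefs[row] = model.coef_
        intercepts[row] = model.intercept_
    if n_classes == 2:
        coefs[0] = -coefs[1]
        intercepts[0] = 1.0 - intercepts[1]
    selected = np.any(np.abs(coefs) > 1e-10, axis=0)
    selected[unpen_idx] = True
    return selected, coefs, intercepts, (mu, sd)


def lasso_select(
    table: LabeledFeatureTable,
    n_repeats: int = 100,
    split_fraction: float = 0.7,
    threshold: float = 0.5,
    seed: int = 0,
    cv_folds: int = 5,
) -> SelectionReport:
    """Repeated-split LASSO with frequency ranking.

    Per repeat: stratified train/test split, L1-penalized one-vs-rest linear
    fit (penalty by internal CV on the training split), record the
    nonzero-coefficient parameters and the test-split BER.  Frequencies are
    selection counts / n_repeats; parameters at or above ``threshold``
    frequency are retained.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    table = table.imputed()
    X_df = table.X
    const = X_df.columns[X_df.std(numeric_only=True) == 0]
    if len(const):
        import warnings

        warnings.warn(
            f"dropping constant columns: {list(const)}", stacklevel=2
        )
        X_df = X_df.drop(columns=const)
    X = X_df.to_numpy(dtype=float)
    y = table.y
    classes = np.unique(y)
    unpen_idx = np.array(
        [X_df.columns.get_loc(c) for c in table.unpenalized if c in X_df.columns],
        dtype=int,
    )
    counts = np.zeros(X.shape[1])
    bers = np.zeros(n_repeats)
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        Xtr, Xte, ytr, yte = train_test_split(
            X,
            y,
            train_size=split_fraction,
            stratify=y,
            random_state=rep_seed,
        )
        selected, coefs, intercepts, (mu, sd) = _fit_ovr_lasso(
            Xtr, ytr, classes, cv_folds, rep_seed, unpen_idx
        )
        counts += selected
        scores = ((Xte - mu) / sd) @ coefs.T + intercepts
        y_pred = classes[np.argmax(scores, axis=1)]
        bers[rep] = multiclass_ber(yte, y_pred)
    freqs = pd.Series(counts / n_repeats, index=X_df.columns).sort_values(
        ascending=False, kind="stable"
    )
    return SelectionReport(freqs, bers, threshold)


# ---------------------------------------------------------------------------
# stepwise reduction
# ---------------------------------------------------------------------------


def _cv_ber(
    X: np.ndarray, y: np.ndarray, cols: list[int], cv_folds: int, seed: int
) -> float:
    """Cross-validated BER of a ridge-free linear one-vs-rest classifier on
    the selected columns (nearest-score assignment)."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    classes, y_idx = np.unique(y, return_inverse=True)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    bers = []
    Xs = X[:, cols]
    for tr, te in skf.split(Xs, y_idx):
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(Xs[tr], y_idx[tr])
        pred = clf.predict(Xs[te])
        bers.append(multiclass_ber(y_idx[te], pred))
    return float(np.mean(bers))


def stepwise_reduce(
    table: LabeledFeatureTable,
    candidate_params: list[str],
    seed: int = 0,
    cv_folds: int = 5,
    tol: float = 1e-9,
) -> tuple[list[str], list[tuple[int, float]]]:
    """Greedy forward-backward search minimizing cross-validated BER.

    Returns (selected parameter list, trace of (subset size, best CV BER)).
    """
    if not candidate_params:
        raise ValidationError("candidate_params must be non-empty")
    table = table.imputed()
    cols = [c for c in candidate_params if c in table.X.columns]
    X = table.X[cols].to_numpy(dtype=float)
    y = table.y
    remaining = list(range(len(cols)))
    current: list[int] = []
    trace: list[tuple[int, float]] = []
    best_ber = math.inf
    while remaining:
        scores = [
            (_cv_ber(X, y, current + [j], cv_folds, seed), j) for j in remaining
        ]
        ber_j, j = min(scores)
        if current and ber_j >= best_ber - tol:
            break
        current.append(j)
        remaining.remove(j)
        best_ber = ber_j
        # backward pass: drop any member whose removal improves the CV BER
        improved = True
        while improved and len(current) > 1:
            improved = False
            for k in list(current):
                if k == j:
                    continue
                reduced = [c for c in current if c != k]
                ber_red = _cv_ber(X, y, reduced, cv_folds, seed)
                if ber_red < best_ber - tol:
                    current = reduced
                    best_ber = ber_red
                    improved = True
                    break
        trace.append((len(current), best_ber))
    return [cols[j] for j in current], trace
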