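"""Multinomial subtype classifier with cross-validated ROC/AUC.

A ridge-penalised multinomial (softmax) logistic regression is trained on
the marker-panel features and evaluated with stratified k-fold
cross-validation: features are standardised on each training split, the
held-out class probabilities are pooled across folds, and ROC curves are
computed from the pooled out-of-fold probabilities — one-vs-rest per
class, and one-vs-one per class pair (the headline pairwise AUCs, using
the conditional probability p_i / (p_i + p_j) restricted to the two
classes' samples).

AUC uses the Mann-Whitney midrank formulation, so ties contribute 1/2.
The fit is a convex problem and the whole procedure is deterministic
given (X, y, seed, cv_folds, ridge_lambda).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_model import DataError, log

_MAX_ITER = 5000
_SD_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC for binary ``labels`` ranked by ``scores``.

    AUC is the Mann-Whitney U statistic normalised by n_pos * n_neg
    (midranks, so ties count 1/2); the ROC is a threshold sweep over the
    unique scores, starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be 1-D and the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both label values must be present to compute ROC/AUC")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # keep only the last point of each tied-score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


# ---------------------------------------------------------------------------
# Multinomial fit
# ---------------------------------------------------------------------------

def fit_multinomial(
    X: np.ndarray, y: np.ndarray, ridge_lambda: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fit softmax regression; returns (classes, coefficients).

    ``coefficients`` has shape (n_classes, n_features + 1) with the
    intercept in the last column.  The objective is the multinomial
    log-likelihood minus (ridge_lambda / 2) * ||W||^2 over the non-intercept
    weights; with ridge_lambda = 0 the fit is unpenalised and perfectly
    separable data cannot converge — the error suggests a positive lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if ridge_lambda < 0:
        raise DataError("ridge_lambda must be non-negative")
    if len(np.unique(y)) < 2:
        raise DataError("need at least 2 classes to fit a classifier")
    C = np.inf if ridge_lambda == 0 else 1.0 / ridge_lambda
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=_MAX_ITER, tol=1e-6)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            clf.fit(X, y)
        except Exception as exc:  # ConvergenceWarning escalated, or solver failure
            raise DataError(
                f"multinomial fit did not converge within {_MAX_ITER} iterations "
                "(perfectly separable data needs ridge_lambda > 0): " + str(exc)
            ) from exc
    if np.max(clf.n_iter_) >= _MAX_ITER:
        raise DataError(
            f"multinomial fit did not converge within {_MAX_ITER} iterations; "
            "increase ridge_lambda"
        )
    if ridge_lambda == 0:
        proba = clf.predict_proba(X)
        idx = np.searchsorted(clf.classes_, y)
        if np.all(proba[np.arange(len(y)), idx] > 1 - 1e-5):
            raise DataError(
                "data are perfectly separable and the unpenalised likelihood "
                "is unbounded; use ridge_lambda > 0"
            )
    coef = np.column_stack([clf.coef_, clf.intercept_])
    if len(clf.classes_) == 2:
        # expand sklearn's single binary row to the symmetric 2-row softmax form
        coef = np.vstack([-coef / 2.0, coef / 2.0])
    return clf.classes_, coef


def predict_proba(X: np.ndarray, classes: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Softmax probabilities for coefficients from :func:`fit_multinomial`."""
    X = np.asarray(X, dtype=float)
    logits = X @ coef[:, :-1].T + coef[:, -1]
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))


def penalized_log_likelihood(
    X: np.ndarray, y: np.ndarray, classes: np.ndarray, coef: np.ndarray,
    ridge_lambda: float,
) -> float:
    """The objective maximised by :func:`fit_multinomial` (intercept unpenalised)."""
    proba = predict_proba(X, classes, coef)
    idx = np.searchsorted(classes, np.asarray(y))
    ll = float(np.sum(np.log(proba[np.arange(len(y)), idx] + 1e-300)))
    return ll - 0.5 * ridge_lambda * float(np.sum(coef[:, :-1] ** 2))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClassifierReport:
    classes: list[str]
    auc_ovr: dict[str, float]                      # one-vs-rest, pooled OOF
    roc_ovr: dict[str, np.ndarray]                 # class -> (k, 2) FPR/TPR points
    auc_pairwise: dict[tuple[str, str], float]     # one-vs-one per class pair
    fold_assignments: dict[str, int] | dict[int, int]
    coefficients: np.ndarray                       # full-data fit, classes x (p+1)
    oof_proba: np.ndarray                          # samples x classes
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "auc_ovr": {k: v for k, v in self.auc_ovr.items()},
            "auc_pairwise": {f"{a}|{b}": v for (a, b), v in self.auc_pairwise.items()},
            "fold_assignments": {str(k): int(v) for k, v in self.fold_assignments.items()},
            "config": self.config,
        }


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd < _SD_FLOOR, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 10,
    ridge_lambda: float = 1.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> ClassifierReport:
    """Stratified k-fold CV of the multinomial classifier.

    Per fold: standardise on the training split, fit, store held-out
    probabilities.  Pooled out-of-fold probabilities give one single ROC
    per class (one-vs-rest) and one AUC per class pair (one-vs-one on the
    two classes' samples).  If the smallest class has fewer members than
    ``cv_folds`` the fold count is reduced to keep every fold stratified.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < 2:
        small = classes[class_counts.argmin()]
        raise DataError(f"class {small!r} has < 2 samples; cannot cross-validate")
    n_splits = int(min(cv_folds, class_counts.min()))
    if n_splits < cv_folds:
        log.info("reducing folds from %d to %d (smallest class)", cv_folds, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    oof = np.zeros((len(y), len(classes)))
    fold_of = np.empty(len(y), dtype=int)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = _standardize(X[tr], X[te])
        fit_classes, coef = fit_multinomial(Xtr, y[tr], ridge_lambda)
        proba = predict_proba(Xte, fit_classes, coef)
        # align columns in case a class is absent from this training split
        col = {c: i for i, c in enumerate(fit_classes)}
        for i, c in enumerate(classes):
            if c in col:
                oof[te, i] = proba[:, col[c]]
        fold_of[te] = k
    auc_ovr: dict[str, float] = {}
    roc_ovr: dict[str, np.ndarray] = {}
    for i, c in enumerate(classes):
        points, auc = roc_auc(oof[:, i], y == c)
        auc_ovr[str(c)] = auc
        roc_ovr[str(c)] = points
    auc_pair: dict[tuple[str, str], float] = {}
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            mask = (y == classes[i]) | (y == classes[j])
            pi, pj = oof[mask, i], oof[mask, j]
            cond = pi / np.maximum(pi + pj, 1e-300)
            _, auc = roc_auc(cond, y[mask] == classes[i])
            auc_pair[(str(classes[i]), str(classes[j]))] = auc
    Xs, _ = _standardize(X, X)
    _, full_coef = fit_multinomial(Xs, y, ridge_lambda)
    ids = sample_ids if sample_ids is not None else list(range(len(y)))
    return ClassifierReport(
        classes=[str(c) for c in classes],
        auc_ovr=auc_ovr,
        roc_ovr=roc_ovr,
        auc_pairwise=auc_pair,
        fold_assignments={i: int(f) for i, f in zip(ids, fold_of)},
        coefficients=full_coef,
        oof_proba=oof,
        config={"cv_folds": n_splits, "ridge_lambda": ridge_lambda, "seed": seed},
    )
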