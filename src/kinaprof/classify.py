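"""PLS-DA classification of benign versus malignant profiles.

A class prediction model is built on the full peptide matrix, without prior
selection of discriminative peptides, by partial least squares discriminant
analysis: the class is coded benign = +1 / malignant = -1 and latent
components are extracted sequentially (NIPALS) to maximize covariance
between the autoscaled peptide matrix and the coded class. Applying the
model to a sample yields a signed prediction score; score > 0 predicts
benign, score <= 0 malignant. Performance is estimated by leave-one-out
cross-validation, with centering and scaling recomputed inside every
training fold, and judged against a permutation null in which the class
labels are randomly reassigned and the full cross-validation repeated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFoldError, InvalidArgumentError

CLASS_CODE = {"benign": 1.0, "malignant": -1.0}


def _coded(y) -> np.ndarray:
    y = np.asarray(y)
    unknown = set(np.unique(y)) - set(CLASS_CODE)
    if unknown:
        raise InvalidArgumentError(
            f"labels must be 'benign'/'malignant', got extra {sorted(unknown)}"
        )
    return np.array([CLASS_CODE[v] for v in y])


@dataclass
class ClassifierModel:
    """A fitted PLS-DA model (everything needed for out-of-sample scoring)."""

    weights: np.ndarray  # p x a, unit-norm X-weight vectors
    x_loadings: np.ndarray  # p x a
    y_loadings: np.ndarray  # a
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coef: np.ndarray  # p, regression vector in autoscaled X space
    n_components: int
    peptide_ids: list | None = None

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return ((X - self.x_mean) / self.x_scale) @ self.coef + self.y_mean


@dataclass
class ClassifierResult:
    """Per-sample LOOCV scores with truth, prediction, and fold identity."""

    table: pd.DataFrame  # columns: score, predicted, true, fold

    @property
    def accuracy(self) -> float:
        return float((self.table["predicted"] == self.table["true"]).mean())

    @property
    def misclassification_rate(self) -> float:
        return 1.0 - self.accuracy


@dataclass
class PermutationResult:
    observed_rate: float
    null_rates: np.ndarray
    p_value: float


def _fit_core(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on centered/scaled data; returns (W, P, Q, coef)."""
    n, p = Xc.shape
    Xd = Xc.copy()
    yd = yc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p_load = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd -= np.outer(t, p_load)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a] = w, p_load, q
        used = a + 1
    W, P, Q = W[:, :used], P[:, :used], Q[:used]
    if used == 0:
        return W, P, Q, np.zeros(p)
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return W, P, Q, coef


def fit_plsda(X, y, n_components: int = 2) -> ClassifierModel:
    """Fit PLS-DA on autoscaled X against the +1/-1 class coding."""
    peptide_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("X contains missing or non-finite cells")
    ycode = _coded(y)
    if len(np.unique(ycode)) < 2:
        raise InvalidArgumentError("both classes must be present to fit a classifier")
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise InvalidArgumentError(
            f"n_components must lie in [1, min(n_samples - 1, n_peptides)] = "
            f"[1, {min(n - 1, p)}], got {n_components}"
        )
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    Xc = (X - x_mean) / x_scale
    y_mean = float(ycode.mean())
    W, P, Q, coef = _fit_core(Xc, ycode - y_mean, n_components)
    return ClassifierModel(
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        coef=coef,
        n_components=W.shape[1],
        peptide_ids=peptide_ids,
    )


def predict_class(scores: np.ndarray) -> np.ndarray:
    """score > 0 is benign, strictly; ties at exactly 0 go malignant."""
    return np.where(np.asarray(scores) > 0, "benign", "malignant")


def _check_folds(y: np.ndarray):
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise DegenerateFoldError(
            "leave-one-out needs at least 2 samples per class so every "
            "training fold keeps both classes"
        )


def loocv_scores(X, y, n_components: int = 2) -> ClassifierResult:
    """Signed prediction score for every sample from a model fit without it."""
    sample_ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(y)))
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    _check_folds(ya)
    scores = np.empty(len(ya))
    for i in range(len(ya)):
        keep = np.arange(len(ya)) != i
        model = fit_plsda(Xa[keep], ya[keep], n_components)
        scores[i] = model.predict_scores(Xa[i])[0]
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "score": scores,
            "predicted": predict_class(scores),
            "true": ya,
            "fold": np.arange(len(ya)),
        }
    ).set_index("sample_id")
    return ClassifierResult(table=table)


def _kfold_assignment(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified fold labels: shuffle within class, deal round-robin."""
    folds = np.empty(len(y), dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _cv_misclassification(
    Xa: np.ndarray, ya: np.ndarray, n_components: int, folds, rng: np.random.Generator
) -> float:
    if folds == "loo":
        fold_of = np.arange(len(ya))
        k = len(ya)
    else:
        k = int(folds)
        fold_of = _kfold_assignment(ya, k, rng)
    wrong = 0
    for f in range(k):
        test = fold_of == f
        if not test.any():
            continue
        ytr = ya[~test]
        if len(np.unique(ytr)) < 2:
            raise DegenerateFoldError(f"training fold {f} contains a single class")
        model = fit_plsda(Xa[~test], ytr, n_components)
        pred = predict_class(model.predict_scores(Xa[test]))
        wrong += int((pred != ya[test]).sum())
    return wrong / len(ya)


def permutation_test(
    X,
    y,
    B: int = 500,
    folds="loo",
    seed: int = 0,
    n_components: int = 2,
) -> PermutationResult:
    """Label-permutation null for the cross-validated misclassification rate.

    The full cross-validation is repeated B times with class labels randomly
    reassigned (class sizes preserved); p = (1 + #{null rate <= observed}) /
    (B + 1), so p can never reach zero.
    """
    if B < 1:
        raise InvalidArgumentError("B must be >= 1")
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    _check_folds(ya)
    rng = np.random.default_rng(seed)
    observed = _cv_misclassification(Xa, ya, n_components, folds, rng)
    null_rates = np.empty(B)
    for b in range(B):
        yb = rng.permutation(ya)
        null_rates[b] = _cv_misclassification(Xa, yb, n_components, folds, rng)
    p = (1 + int((null_rates <= observed).sum())) / (B + 1)
    return PermutationResult(observed_rate=observed, null_rates=null_rates, p_value=p)


def confusion_metrics(result: ClassifierResult) -> dict:
    """Confusion-matrix ratios with malignant as the positive class.

    Undefined ratios (zero denominator) are reported as None, not 0.
    """
    t = result.table
    if len(t) == 0:
        raise InvalidArgumentError("empty classifier result")
    pred_pos = t["predicted"] == "malignant"
    true_pos = t["true"] == "malignant"
    tp = int((pred_pos & true_pos).sum())
    tn = int((~pred_pos & ~true_pos).sum())
    fp = int((pred_pos & ~true_pos).sum())
    fn = int((~pred_pos & true_pos).sum())

    def ratio(num, den):
        return num / den if den else None

    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "accuracy": (tp + tn) / len(t),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }
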