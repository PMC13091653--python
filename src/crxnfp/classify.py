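"""Classifiers and metrics over reaction fingerprints.

KNN classification uses exact exhaustive cosine-similarity search (majority
vote among the k most similar references; ties broken by the single nearest
neighbor among the tied classes). The MLP classifier is a thin wrapper over
scikit-learn's ``MLPClassifier`` with the evaluation protocol used for
fingerprint benchmarking: repeated random train/test splits with per-repeat
test accuracy.

Metrics: accuracy, the multiclass Matthews correlation coefficient in its
covariance form, and the confusion-entropy measure CEN (0 for a perfect
classifier, larger when misclassifications are spread over many class pairs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = [
    "ConfusionMatrix",
    "CosineKNNClassifier",
    "knn_classify",
    "train_mlp",
    "confusion_matrix",
    "metrics",
    "accuracy_score",
    "matthews_corrcoef",
    "confusion_entropy",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square confusion matrix (rows = truth, columns = prediction)."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label list length must match matrix size")
        if np.any(counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


def confusion_matrix(y_true: Sequence, y_pred: Sequence) -> ConfusionMatrix:
    """Build a ConfusionMatrix over the union of observed labels."""
    labels = tuple(sorted(set(y_true) | set(y_pred), key=str))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding vector; cosine similarity undefined")
    return X / norms


class CosineKNNClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbor classifier under cosine similarity.

    Exact exhaustive search; prediction is the majority label among the k most
    similar references, with ties broken by the label of the single most
    similar neighbor belonging to one of the tied classes.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: np.ndarray, y: Sequence) -> "CosineKNNClassifier":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = np.asarray(X, dtype=float)
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds number of references {X.shape[0]}")
        self.X_ = _normalize_rows(X)
        self.y_ = np.asarray(list(y), dtype=object)
        self.classes_ = np.array(sorted(set(self.y_), key=str), dtype=object)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Q = _normalize_rows(X)
        sims = Q @ self.X_.T  # (n_query, n_ref)
        # stable ranking: descending similarity, ascending reference index on ties
        order = np.lexsort((np.arange(sims.shape[1])[None, :].repeat(len(Q), 0), -sims), axis=1)
        top = order[:, : self.k]
        preds = []
        for ranked in top:
            votes: dict = {}
            for ref_idx in ranked:
                lab = self.y_[ref_idx]
                votes[lab] = votes.get(lab, 0) + 1
            best = max(votes.values())
            tied = {lab for lab, c in votes.items() if c == best}
            if len(tied) == 1:
                preds.append(next(iter(tied)))
            else:
                # nearest neighbor whose label is among the tied classes
                preds.append(next(self.y_[i] for i in ranked if self.y_[i] in tied))
        return np.asarray(preds, dtype=object)


def knn_classify(
    reference_embeddings: np.ndarray,
    reference_labels: Sequence,
    query_embeddings: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Functional form of :class:`CosineKNNClassifier`."""
    clf = CosineKNNClassifier(k=k).fit(reference_embeddings, reference_labels)
    return clf.predict(query_embeddings)


def train_mlp(
    features: np.ndarray,
    labels: Sequence,
    hidden_nodes: int = 512,
    epochs: int = 20,
    split_fraction: float = 0.2,
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated random-split MLP evaluation (one hidden layer).

    Each repeat draws a fresh stratified train/test split, fits an MLP with a
    single ``hidden_nodes``-wide hidden layer for ``epochs`` epochs, and
    records the held-out accuracy. Returns the per-repeat accuracies, their
    mean and standard deviation, and the fitted models.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(list(labels), dtype=object)
    if len(set(y)) < 2:
        raise ValueError("need at least two classes")
    accuracies = []
    models = []
    for rep in range(repeats):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=split_fraction, random_state=seed + rep, stratify=y
        )
        model = MLPClassifier(
            hidden_layer_sizes=(hidden_nodes,),
            max_iter=epochs,
            random_state=seed + rep,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X_tr, y_tr)
        accuracies.append(float(np.mean(model.predict(X_te) == y_te)))
        models.append(model)
    acc = np.asarray(accuracies)
    return {
        "accuracies": acc,
        "mean": float(acc.mean()),
        "std": float(acc.std(ddof=1)) if repeats > 1 else 0.0,
        "models": models,
    }


# -- metrics -------------------------------------------------------------


def accuracy_score(cm: ConfusionMatrix) -> float:
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(counts) / total)


def matthews_corrcoef(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient, covariance form.

    MCC = (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    with c the number of correct predictions, s the sample count, t_k the
    true and p_k the predicted count of class k. Degenerate denominators
    (a single observed or predicted class) give 0.
    """
    C = np.asarray(cm.counts, dtype=float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # true counts per class
    p = C.sum(axis=0)  # predicted counts per class
    num = c * s - float(t @ p)
    denom = math.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if denom == 0.0:
        return 0.0
    return float(num / denom)


def confusion_entropy(cm: ConfusionMatrix) -> float:
    """Confusion-entropy measure CEN (Wei et al. style).

    For class j the misclassification probabilities are normalized by the sum
    of row j and column j; their entropies (log base 2(N-1), base 2 for the
    two-class case) are weighted by the share of samples touching class j and
    summed. Zero iff the matrix is diagonal.
    """
    C = np.asarray(cm.counts, dtype=float)
    n = C.shape[0]
    if n < 2:
        return 0.0
    s = C.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    base = 2.0 * (n - 1)
    log_base = math.log(base) if base > 1 else math.log(2.0)
    total = 0.0
    for j in range(n):
        denom = C[j, :].sum() + C[:, j].sum()
        if denom == 0:
            continue
        w = denom / (2.0 * s)
        ent = 0.0
        for k in range(n):
            if k == j:
                continue
            for p in (C[j, k] / denom, C[k, j] / denom):
                if p > 0:
                    ent -= p * math.log(p) / log_base
        total += w * ent
    return float(total)


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, MCC and CEN of a confusion matrix."""
    return {
        "accuracy": accuracy_score(cm),
        "mcc": matthews_corrcoef(cm),
        "cen": confusion_entropy(cm),
    }
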