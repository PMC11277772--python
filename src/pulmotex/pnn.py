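"""Probabilistic neural network (PNN) classifier.

A PNN is a Parzen-window density estimator with a Bayes decision layer:
training stores the (standardized) feature vectors verbatim as pattern
units; classification evaluates a Gaussian kernel density per class

    f_k(x) = (1/m_k) sum_{w in class k} exp(-||x - w||^2 / (2 sigma^2))

and decides ``argmax_k  prior_k * cost_k * f_k(x)`` (ties break to the
smallest class label). For two classes the equivalent summation-unit form
adds the class-A kernels to ``v_b`` times the class-B kernels, with the
negative summation weight

    v_b = - (prior_b * cost_b * m_a) / (prior_a * cost_a * m_b)

and declares class A iff the total is positive; this binary unit is kept
alongside the argmax form and tested equivalent.

Features are standardized to zero mean and unit variance using the
training data, so a single scalar bandwidth ``sigma`` is meaningful
across features.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.special import logsumexp

from pulmotex.types import FeatureTable

__all__ = ["PNNModel", "fit_pnn", "pnn_classify", "pnn_scores", "summation_weight"]


@dataclass
class PNNModel:
    """Stored patterns grouped by class, plus priors, costs and bandwidth."""

    patterns: dict[int, np.ndarray]     # class -> (m_k, M) standardized patterns
    priors: dict[int, float]
    costs: dict[int, float]
    sigma: float
    mean_: np.ndarray
    scale_: np.ndarray

    @property
    def classes(self) -> list[int]:
        return sorted(self.patterns)

    @property
    def counts(self) -> dict[int, int]:
        return {k: v.shape[0] for k, v in self.patterns.items()}

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean_) / self.scale_


def fit_pnn(
    table: FeatureTable,
    sigma: float = 0.3,
    priors: dict[int, float] | None = None,
    costs: dict[int, float] | None = None,
) -> PNNModel:
    """Store the training patterns ("training" allocates, never iterates).

    ``priors`` default to class frequencies; explicit priors that do not
    sum to 1 are normalized with a warning. ``costs`` default to 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    classes = [int(c) for c in table.classes]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    mean = table.features.mean(axis=0)
    scale = table.features.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    standardized = (table.features - mean) / scale

    patterns = {c: standardized[table.labels == c] for c in classes}
    if any(p.shape[0] == 0 for p in patterns.values()):
        raise ValueError("every class needs at least one pattern")

    if priors is None:
        priors = {c: patterns[c].shape[0] / table.n_samples for c in classes}
    else:
        priors = {int(c): float(v) for c, v in priors.items()}
        total = sum(priors.values())
        if not np.isclose(total, 1.0):
            warnings.warn(f"priors sum to {total:.6g}; normalizing", stacklevel=2)
            priors = {c: v / total for c, v in priors.items()}
    costs = {c: 1.0 for c in classes} if costs is None else {
        int(c): float(v) for c, v in costs.items()
    }
    return PNNModel(patterns, priors, costs, float(sigma), mean, scale)


def _log_class_scores(model: PNNModel, X: np.ndarray) -> np.ndarray:
    """(n_queries, n_classes) of ``log(prior_k cost_k f_k(x))``.

    Everything stays in the log domain so tiny bandwidths (the 1-NN
    limit) do not underflow.
    """
    Xs = model.standardize(X)
    out = np.empty((Xs.shape[0], len(model.classes)))
    two_s2 = 2.0 * model.sigma**2
    for ci, c in enumerate(model.classes):
        W = model.patterns[c]
        d2 = np.sum((Xs[:, None, :] - W[None, :, :]) ** 2, axis=2)
        log_f = logsumexp(-d2 / two_s2, axis=1) - np.log(W.shape[0])
        out[:, ci] = np.log(model.priors[c] * model.costs[c]) + log_f
    return out


def pnn_scores(model: PNNModel, X: np.ndarray) -> np.ndarray:
    """Normalized posterior scores per class (rows sum to 1)."""
    log_scores = _log_class_scores(model, X)
    shifted = log_scores - log_scores.max(axis=1, keepdims=True)
    raw = np.exp(shifted)
    return raw / raw.sum(axis=1, keepdims=True)


def pnn_classify(model: PNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bayes decision ``argmax_k prior_k cost_k f_k(x)`` plus the
    normalized per-class scores; ties go to the smallest class label."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_.size:
        raise ValueError("query dimension mismatch")
    scores = pnn_scores(model, X)
    classes = np.array(model.classes)
    pred = classes[np.argmax(scores, axis=1)]  # argmax ties -> lowest index
    return pred, scores


def summation_weight(model: PNNModel, class_a: int, class_b: int) -> float:
    """The summation-unit weight for the binary decision between class_a
    (the reference class) and class_b:

        v_b = -(prior_b cost_b m_a) / (prior_a cost_a m_b)

    The binary unit computes ``sum kernels_a + v_b sum kernels_b`` and
    declares class_a iff the total is positive.
    """
    counts = model.counts
    for c in (class_a, class_b):
        if c not in counts:
            raise ValueError(f"class {c} not in model")
    return -(
        model.priors[class_b] * model.costs[class_b] * counts[class_a]
    ) / (model.priors[class_a] * model.costs[class_a] * counts[class_b])


def binary_decide(model: PNNModel, x: np.ndarray, class_a: int, class_b: int) -> int:
    """Two-class decision through the summation unit (kept for fidelity
    with the layered formulation; equivalent to the argmax rule)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xs = model.standardize(x)
    two_s2 = 2.0 * model.sigma**2

    def kernel_sum(c: int) -> float:
        W = model.patterns[c]
        return float(np.sum(np.exp(-np.sum((xs - W) ** 2, axis=1) / two_s2)))

    v_b = summation_weight(model, class_a, class_b)
    total = kernel_sum(class_a) + v_b * kernel_sum(class_b)
    return class_a if total > 0 else class_b
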