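"""Probabilistic neural network (PNN) classifier.

A PNN is a single-pass Parzen-window / Bayes classifier with four layers:
the input layer receives a feature vector x, each pattern-layer unit holds
one training vector w_i and fires a Gaussian kernel
phi_i(x) = exp(-||x - w_i||^2 / (2 sigma^2)), the summation layer averages
the activations per class (optionally cost-weighted, with an additive
per-class bias), and the output layer picks the argmax class.

The per-pattern multipliers alpha_i in [0,1] and per-class biases b_c in
[0,1] are the quantities the metaheuristic trainer tunes; at alpha=1, b=0,
unit costs the model is exactly the classical PNN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LabeledDataset",
    "PNNModel",
    "fit_pnn",
    "kernel_activations",
    "class_scores",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class LabeledDataset:
    """Tabular classification data: n×d features plus n class labels.

    ``class_set`` fixes the class order used for score vectors and
    deterministic tie-breaking; by default it is the sorted set of labels.
    """

    features: np.ndarray
    labels: np.ndarray
    class_set: list = field(default=None)
    name: str = "dataset"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must be a vector with one entry per row")
        if self.features.shape[0] < 2:
            raise ValueError("need at least 2 instances")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain missing or non-finite values")
        if self.class_set is None:
            self.class_set = sorted(np.unique(self.labels).tolist())
        else:
            self.class_set = list(self.class_set)
            if set(np.unique(self.labels)) - set(self.class_set):
                raise ValueError("labels contain classes outside class_set")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def class_counts(self) -> np.ndarray:
        return np.array([(self.labels == c).sum() for c in self.class_set])


@dataclass
class PNNModel:
    """Fitted PNN: pattern-layer centers plus the tunable multipliers.

    Fields
    ------
    centers : n_tr×d matrix of training vectors (pattern weights w_i)
    center_labels : class of each center
    sigma : shared Gaussian smoothing bandwidth (> 0)
    pattern_weights : per-center multipliers alpha_i in [0,1]
    class_biases : per-class additive biases b_c in [0,1]
    class_costs : per-class cost/prior multipliers C_c
    bias_scale : lambda_b, scales the bias term in the summation layer
    """

    centers: np.ndarray
    center_labels: np.ndarray
    class_set: list
    sigma: float
    pattern_weights: np.ndarray
    class_biases: np.ndarray
    class_costs: np.ndarray
    bias_scale: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.centers = np.asarray(self.centers, dtype=float)
        self.pattern_weights = np.asarray(self.pattern_weights, dtype=float)
        self.class_biases = np.asarray(self.class_biases, dtype=float)
        self.class_costs = np.asarray(self.class_costs, dtype=float)
        n_tr = self.centers.shape[0]
        c = len(self.class_set)
        if self.pattern_weights.shape != (n_tr,):
            raise ValueError("pattern_weights must have one entry per center")
        if self.class_biases.shape != (c,) or self.class_costs.shape != (c,):
            raise ValueError("class_biases/class_costs must have one entry per class")
        if ((self.pattern_weights < 0) | (self.pattern_weights > 1)).any():
            raise ValueError("pattern_weights must lie in [0, 1]")
        if ((self.class_biases < 0) | (self.class_biases > 1)).any():
            raise ValueError("class_biases must lie in [0, 1]")
        # n_c per class, and a one-hot membership matrix used for vectorized scoring
        self._membership = np.stack(
            [(np.asarray(self.center_labels) == cls) for cls in self.class_set]
        ).astype(float)  # C × n_tr
        self.class_counts = self._membership.sum(axis=1).astype(int)

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]


def fit_pnn(train: LabeledDataset, sigma: float = 0.1) -> PNNModel:
    """Single-pass fit: centers are the training rows, alpha=1, b=0, C_c=1.

    Default sigma=0.1 matches the benchmark configuration; it is exposed but
    never tuned by the optimizer.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("degenerate class structure: training data has a single class")
    c = train.n_classes
    return PNNModel(
        centers=train.features.copy(),
        center_labels=train.labels.copy(),
        class_set=list(train.class_set),
        sigma=float(sigma),
        pattern_weights=np.ones(train.n),
        class_biases=np.zeros(c),
        class_costs=np.ones(c),
    )


def kernel_activations(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """Pattern-layer activations phi_i(x) = exp(-||x-w_i||^2 / (2 sigma^2))."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ValueError(f"expected a feature vector of length {model.d}")
    sq = ((model.centers - x) ** 2).sum(axis=1)
    return np.exp(-sq / (2.0 * model.sigma**2))


def _activation_matrix(model: PNNModel, X: np.ndarray) -> np.ndarray:
    sq = cdist(X, model.centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * model.sigma**2))


def _scores_from_activations(
    model: PNNModel, phi: np.ndarray, counts: Optional[np.ndarray] = None
) -> np.ndarray:
    """Summation layer: f_c = C_c * (1/n_c) * sum_{i in c} alpha_i phi_i + lambda_b * b_c.

    ``counts`` overrides the per-row class denominators (used by
    leave-one-out mode where the excluded center shrinks its own class count).
    """
    weighted = phi * model.pattern_weights  # m × n_tr
    sums = weighted @ model._membership.T  # m × C
    if counts is None:
        counts = np.broadcast_to(model.class_counts, sums.shape)
    counts = np.maximum(counts, 1)
    return (
        model.class_costs * sums / counts
        + model.bias_scale * model.class_biases
    )


def class_scores(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """Per-class summation-layer outputs for one feature vector."""
    phi = kernel_activations(model, x)
    return _scores_from_activations(model, phi[None, :])[0]


def predict(
    model: PNNModel,
    X: np.ndarray,
    leave_one_out: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Output layer: argmax class per row, ties broken toward the earliest
    class in ``class_set``.

    With ``leave_one_out=True`` X must be the training matrix in center
    order: row i is scored with center i excluded (and its class denominator
    reduced by one), which keeps training-accuracy fitness from saturating
    on trivial self matches.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d:
        raise ValueError(f"expected an m×{model.d} matrix")
    phi = _activation_matrix(model, X)
    counts = None
    if leave_one_out:
        if X.shape[0] != model.n_centers:
            raise ValueError("leave-one-out mode requires X to be the training matrix")
        np.fill_diagonal(phi, 0.0)
        counts = np.broadcast_to(model.class_counts, (X.shape[0], len(model.class_set))).copy()
        counts = counts.astype(float)
        own = model._membership.T[np.arange(X.shape[0])]  # m × C one-hot of own class
        counts -= own
    scores = _scores_from_activations(model, phi, counts)
    idx = np.argmax(scores, axis=1)  # np.argmax takes the first max: earliest class wins ties
    labels = np.asarray(model.class_set, dtype=np.asarray(model.center_labels).dtype)[idx]
    return labels, scores


def save_model(model: PNNModel, path) -> None:
    """Serialize to JSON (round-trip exact for inference)."""
    payload = {
        "centers": model.centers.tolist(),
        "center_labels": np.asarray(model.center_labels).tolist(),
        "class_set": list(model.class_set),
        "sigma": model.sigma,
        "pattern_weights": model.pattern_weights.tolist(),
        "class_biases": model.class_biases.tolist(),
        "class_costs": model.class_costs.tolist(),
        "bias_scale": model.bias_scale,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> PNNModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return PNNModel(
        centers=np.array(payload["centers"], dtype=float),
        center_labels=np.array(payload["center_labels"]),
        class_set=payload["class_set"],
        sigma=payload["sigma"],
        pattern_weights=np.array(payload["pattern_weights"], dtype=float),
        class_biases=np.array(payload["class_biases"], dtype=float),
        class_costs=np.array(payload["class_costs"], dtype=float),
        bias_scale=payload["bias_scale"],
    )
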