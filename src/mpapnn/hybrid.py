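"""MPA-PNN trainer: encode PNN parameters as a bounded vector and let the
Marine Predators Algorithm maximize leave-one-out training accuracy.

Two encodings of the parameter vector theta (all coordinates in [0, 1]):

* ``pattern_bias`` (default): theta = [alpha_1..alpha_n_tr, b_1..b_C] —
  per-pattern kernel multipliers plus per-class biases, dimension n_tr + C.
* ``centers``: theta = [flattened centers (row-major), b_1..b_C] — the
  pattern-layer centers themselves are moved, dimension n_tr*d + C
  (meaningful when features are normalized to [0, 1]).

One individual of the initial population is planted at the identity encoding
(alpha=1, b=0, original centers), so the trained model's fitness can never
fall below the vanilla PNN's leave-one-out training accuracy.
A pure uniform random-search baseline over the same space is included for
budget-matched comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .mpa import ConvergenceTrace, MPAConfig, SearchSpace, optimize
from .pnn import LabeledDataset, PNNModel, fit_pnn, predict

__all__ = [
    "ParameterEncoding",
    "TrainingRun",
    "encoding_dimension",
    "encode",
    "decode",
    "fitness",
    "train_mpa_pnn",
    "train_random_search",
]

EncodingMode = Literal["pattern_bias", "centers"]


@dataclass(frozen=True)
class ParameterEncoding:
    """Layout of the optimized vector for a given training-set shape."""

    mode: EncodingMode
    n_tr: int
    n_classes: int
    d: int

    def __post_init__(self):
        if self.mode not in ("pattern_bias", "centers"):
            raise ValueError(f"unknown encoding mode: {self.mode!r}")
        if min(self.n_tr, self.n_classes, self.d) < 1:
            raise ValueError("n_tr, n_classes and d must all be >= 1")

    @property
    def dimension(self) -> int:
        if self.mode == "pattern_bias":
            return self.n_tr + self.n_classes
        return self.n_tr * self.d + self.n_classes

    def identity_theta(self, base: PNNModel) -> np.ndarray:
        """The vector that reproduces the vanilla PNN (alpha=1, b=0)."""
        if self.mode == "pattern_bias":
            return np.concatenate([np.ones(self.n_tr), np.zeros(self.n_classes)])
        return np.concatenate([base.centers.ravel(), np.zeros(self.n_classes)])


def encoding_dimension(mode: EncodingMode, n_tr: int, n_classes: int, d: int) -> int:
    return ParameterEncoding(mode, n_tr, n_classes, d).dimension


def decode(theta: np.ndarray, encoding: ParameterEncoding, base: PNNModel) -> PNNModel:
    """Materialize the PNN described by theta on top of the fitted base model."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (encoding.dimension,):
        raise ValueError(
            f"theta has length {theta.size}, expected {encoding.dimension}"
        )
    if ((theta < 0) | (theta > 1)).any():
        raise ValueError("theta coordinates must lie in [0, 1]")
    c = encoding.n_classes
    if encoding.mode == "pattern_bias":
        centers = base.centers
        alpha = theta[: encoding.n_tr]
    else:
        centers = theta[: encoding.n_tr * encoding.d].reshape(encoding.n_tr, encoding.d)
        alpha = np.ones(encoding.n_tr)
    return PNNModel(
        centers=centers.copy(),
        center_labels=base.center_labels,
        class_set=base.class_set,
        sigma=base.sigma,
        pattern_weights=alpha.copy(),
        class_biases=theta[-c:].copy(),
        class_costs=base.class_costs.copy(),
        bias_scale=base.bias_scale,
    )


def encode(model: PNNModel, encoding: ParameterEncoding) -> np.ndarray:
    """Inverse of :func:`decode` (exact round trip)."""
    if encoding.mode == "pattern_bias":
        head = model.pattern_weights
    else:
        head = model.centers.ravel()
    return np.concatenate([head, model.class_biases])


class _LOOFitness:
    """Leave-one-out training-accuracy objective with a cached kernel matrix.

    In pattern_bias mode the centers never move, so the n_tr×n_tr activation
    matrix is theta-independent and computed once; evaluating a candidate
    reduces to one matrix-vector product per class.  In centers mode the
    kernels depend on theta and are recomputed per call.
    """

    def __init__(self, encoding: ParameterEncoding, train: LabeledDataset, base: PNNModel):
        self.encoding = encoding
        self.train = train
        self.base = base
        self.labels = np.asarray(train.labels)
        self.membership = base._membership  # C × n_tr
        # per-row LOO class denominators: own class loses its excluded center
        counts = np.broadcast_to(
            base.class_counts.astype(float), (train.n, len(base.class_set))
        ).copy()
        counts -= self.membership.T
        self.loo_counts = np.maximum(counts, 1.0)
        self.own_class_idx = np.array(
            [base.class_set.index(l) for l in self.labels]
        )
        if encoding.mode == "pattern_bias":
            sq = cdist(train.features, base.centers, metric="sqeuclidean")
            phi = np.exp(-sq / (2.0 * base.sigma**2))
            np.fill_diagonal(phi, 0.0)
            self._phi = phi
        else:
            self._phi = None

    def __call__(self, theta: np.ndarray) -> float:
        c = self.encoding.n_classes
        biases = theta[-c:]
        if self._phi is not None:
            alpha = theta[: self.encoding.n_tr]
            sums = (self._phi * alpha) @ self.membership.T
            scores = (
                self.base.class_costs * sums / self.loo_counts
                + self.base.bias_scale * biases
            )
            pred_idx = np.argmax(scores, axis=1)
            return float(np.mean(pred_idx == self.own_class_idx))
        model = decode(theta, self.encoding, self.base)
        pred, _ = predict(model, self.train.features, leave_one_out=True)
        return float(np.mean(pred == self.labels))


def fitness(
    theta: np.ndarray,
    encoding: ParameterEncoding,
    train: LabeledDataset,
    base: PNNModel,
) -> float:
    """Fraction of training points classified correctly in leave-one-out mode.

    For binary labels this is exactly (TP+TN)/(TP+TN+FP+FN); for more classes
    it is the overall fraction correct.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (encoding.dimension,):
        raise ValueError(
            f"theta has length {theta.size}, expected {encoding.dimension}"
        )
    model = decode(theta, encoding, base)
    pred, _ = predict(model, train.features, leave_one_out=True)
    return float(np.mean(pred == np.asarray(train.labels)))


@dataclass
class TrainingRun:
    """Result of one optimization run on one training set."""

    best_theta: np.ndarray
    final_model: PNNModel
    trace: ConvergenceTrace
    seed: int
    evaluations_used: int
    encoding: ParameterEncoding
    best_fitness: float


def train_mpa_pnn(
    train: LabeledDataset,
    pnn_sigma: float = 0.1,
    mpa_config: Optional[MPAConfig] = None,
    encoding_mode: EncodingMode = "pattern_bias",
) -> TrainingRun:
    """Tune PNN weights and biases with MPA (maximizing LOO training accuracy)."""
    config = mpa_config if mpa_config is not None else MPAConfig()
    base = fit_pnn(train, sigma=pnn_sigma)
    encoding = ParameterEncoding(encoding_mode, train.n, train.n_classes, train.d)
    objective = _LOOFitness(encoding, train, base)
    space = SearchSpace.unit(encoding.dimension)
    identity = encoding.identity_theta(base)

    best_theta, best_fit, trace = optimize(
        objective,
        space,
        config,
        direction="maximize",
        seed_positions=identity[None, :],
    )
    n = config.population_size
    evaluations = n + 2 * n * trace.iterations_executed
    return TrainingRun(
        best_theta=best_theta,
        final_model=decode(best_theta, encoding, base),
        trace=trace,
        seed=config.seed,
        evaluations_used=evaluations,
        encoding=encoding,
        best_fitness=best_fit,
    )


def train_random_search(
    train: LabeledDataset,
    pnn_sigma: float = 0.1,
    budget: int = 1000,
    seed: int = 0,
    encoding_mode: EncodingMode = "pattern_bias",
) -> TrainingRun:
    """Uniform random-search baseline over the same [0,1]^dim space.

    Draws ``budget`` independent candidates and keeps the best; the identity
    encoding is deliberately NOT planted, so this is a pure baseline.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base = fit_pnn(train, sigma=pnn_sigma)
    encoding = ParameterEncoding(encoding_mode, train.n, train.n_classes, train.d)
    objective = _LOOFitness(encoding, train, base)
    rng = np.random.default_rng(seed)

    trace = ConvergenceTrace()
    best_theta = None
    best_fit = -np.inf
    for _ in range(budget):
        theta = rng.uniform(size=encoding.dimension)
        value = objective(theta)
        if value > best_fit:
            best_fit = value
            best_theta = theta
        trace.best_fitness_per_iteration.append(best_fit)
    return TrainingRun(
        best_theta=best_theta,
        final_model=decode(best_theta, encoding, base),
        trace=trace,
        seed=seed,
        evaluations_used=budget,
        encoding=encoding,
        best_fitness=float(best_fit),
    )
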