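"""Synthetic labeled-dataset generation and CSV I/O.

Generates offline stand-ins for the 11 UCI benchmark tables the classifier
suite is usually evaluated on: Gaussian class clouds with controllable size,
dimension, imbalance, separation and label noise, plus an interleaved
two-crescent generator for the nonlinear two-feature case.  All features are
min-max scaled to [0, 1], matching the bounded weight/bias search box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pnn import LabeledDataset

__all__ = [
    "DatasetSpec",
    "TABLE_SHAPES",
    "make_gaussian_classes",
    "make_interleaved_nonlinear",
    "make_dataset",
    "make_benchmark_suite",
    "min_max_normalize",
    "load_dataset",
    "save_dataset",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic dataset.

    ``separation`` is the inter-class mean distance in units of the
    within-class spread (1.0); ``noise_rate`` flips that fraction of labels.
    """

    name: str
    n: int
    d: int
    class_proportions: tuple = (0.5, 0.5)
    separation: float = 2.5
    structure: Literal["gaussian_blobs", "interleaved_nonlinear"] = "gaussian_blobs"
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size < 2:
            raise ValueError("need at least 2 classes")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if (props <= 0).any():
            raise ValueError("class proportions must be positive")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")
        if self.structure not in ("gaussian_blobs", "interleaved_nonlinear"):
            raise ValueError(f"unknown structure {self.structure!r}")


def _class_sizes(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n instances to the classes."""
    exact = n * proportions
    sizes = np.floor(exact).astype(int)
    for idx in np.argsort(-(exact - sizes), kind="stable")[: n - sizes.sum()]:
        sizes[idx] += 1
    if (sizes < 2).any():
        raise ValueError("class proportions leave a class with fewer than 2 instances")
    return sizes


def _minmax_scale(features: np.ndarray) -> np.ndarray:
    lo = features.min(axis=0)
    hi = features.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (features - lo) / span
    scaled[:, hi == lo] = 0.0
    return scaled


def _flip_labels(labels: np.ndarray, classes: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate == 0.0:
        return labels
    n_flip = int(round(rate * labels.size))
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    out = labels.copy()
    for i in idx:
        others = classes[classes != labels[i]]
        out[i] = rng.choice(others)
    return out


def make_gaussian_classes(spec: DatasetSpec) -> LabeledDataset:
    """Per-class Gaussian clouds at mean distance ``separation``.

    Class means are placed at separation × random unit directions (class 0 at
    the origin), within-class spread is the unit isotropic normal; features
    are then min-max scaled to [0, 1] and labels flipped at ``noise_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    props = np.asarray(spec.class_proportions, dtype=float)
    sizes = _class_sizes(spec.n, props)
    n_classes = props.size

    means = np.zeros((n_classes, spec.d))
    for k in range(1, n_classes):
        direction = rng.standard_normal(spec.d)
        direction /= np.linalg.norm(direction)
        means[k] = means[0] + spec.separation * direction
    features = []
    labels = []
    for k, size in enumerate(sizes):
        features.append(means[k] + rng.standard_normal((size, spec.d)))
        labels.append(np.full(size, k))
    features = np.vstack(features)
    labels = np.concatenate(labels)
    perm = rng.permutation(spec.n)
    features, labels = features[perm], labels[perm]
    classes = np.arange(n_classes)
    labels = _flip_labels(labels, classes, spec.noise_rate, rng)
    return LabeledDataset(_minmax_scale(features), labels, class_set=classes.tolist(), name=spec.name)


def make_interleaved_nonlinear(spec: DatasetSpec) -> LabeledDataset:
    """Two interleaved crescents in the first two features.

    Class 0 follows the upper half-circle, class 1 the lower half-circle
    offset to interlock with it.  The two manifolds sit about 0.3 apart at
    their closest, so the isotropic jitter is 0.3/separation: the inter-class
    gap is ``separation`` within-class spreads, mirroring the blob generator's
    convention (separation below 0.1 is treated as 0.1).  Extra dimensions
    beyond the first two are filled with uniform noise features.  Not
    linearly separable by construction.
    """
    if spec.d < 2:
        raise ValueError("interleaved_nonlinear needs d >= 2")
    if len(spec.class_proportions) != 2:
        raise ValueError("interleaved_nonlinear is a two-class structure")
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec.n, np.asarray(spec.class_proportions, dtype=float))
    jitter = 0.3 / max(spec.separation, 0.1)

    t0 = rng.uniform(0.0, np.pi, sizes[0])
    arc0 = np.column_stack([np.cos(t0), np.sin(t0)])
    t1 = rng.uniform(0.0, np.pi, sizes[1])
    arc1 = np.column_stack([1.0 - np.cos(t1), 0.5 - np.sin(t1)])
    xy = np.vstack([arc0, arc1]) + jitter * rng.standard_normal((spec.n, 2))
    features = np.empty((spec.n, spec.d))
    features[:, :2] = xy
    if spec.d > 2:
        features[:, 2:] = rng.uniform(size=(spec.n, spec.d - 2))
    labels = np.concatenate([np.zeros(sizes[0], dtype=int), np.ones(sizes[1], dtype=int)])
    perm = rng.permutation(spec.n)
    features, labels = features[perm], labels[perm]
    labels = _flip_labels(labels, np.array([0, 1]), spec.noise_rate, rng)
    return LabeledDataset(_minmax_scale(features), labels, class_set=[0, 1], name=spec.name)


def make_dataset(spec: DatasetSpec) -> LabeledDataset:
    if spec.structure == "gaussian_blobs":
        return make_gaussian_classes(spec)
    return make_interleaved_nonlinear(spec)


# (name, n, d, proportions, structure) — shapes of the 11 UCI benchmarks;
# HSS/AP/Parkinson get imbalanced analogs, Fourclass the nonlinear structure.
TABLE_SHAPES = [
    ("HSS", 283, 3, (0.73, 0.27), "gaussian_blobs"),
    ("PID", 710, 8, (0.65, 0.35), "gaussian_blobs"),
    ("AP", 98, 7, (0.8, 0.2), "gaussian_blobs"),
    ("BC", 265, 10, (0.7, 0.3), "gaussian_blobs"),
    ("LD", 319, 6, (0.58, 0.42), "gaussian_blobs"),
    ("Heart", 250, 13, (0.56, 0.44), "gaussian_blobs"),
    ("GCD", 925, 20, (0.7, 0.3), "gaussian_blobs"),
    ("Parkinson", 180, 23, (0.75, 0.25), "gaussian_blobs"),
    ("SPECTF", 247, 45, (0.79, 0.21), "gaussian_blobs"),
    ("ACA", 638, 14, (0.56, 0.44), "gaussian_blobs"),
    ("Fourclass", 797, 2, (0.64, 0.36), "interleaved_nonlinear"),
]


def make_benchmark_suite(
    master_seed: int = 0,
    separation: float = 2.5,
    noise_rate: float = 0.05,
) -> list[LabeledDataset]:
    """The 11-dataset synthetic suite mirroring the UCI benchmark shapes.

    Each dataset gets a deterministic seed derived from ``master_seed``, so
    the whole suite is reproducible from one integer.
    """
    suite = []
    for offset, (name, n, d, props, structure) in enumerate(TABLE_SHAPES):
        spec = DatasetSpec(
            name=name,
            n=n,
            d=d,
            class_proportions=props,
            separation=separation,
            structure=structure,
            noise_rate=noise_rate,
            seed=(master_seed * 1009 + offset) % (2**31),
        )
        suite.append(make_dataset(spec))
    return suite


def min_max_normalize(
    train: LabeledDataset, test: LabeledDataset
) -> tuple[LabeledDataset, LabeledDataset]:
    """Scale both sets with per-feature min/max learned from train only.

    Test values outside the train range are clipped to [0, 1]; a constant
    train feature maps to 0 everywhere.
    """
    lo = train.features.min(axis=0)
    hi = train.features.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def scale(x):
        out = np.clip((x - lo) / span, 0.0, 1.0)
        out[:, hi == lo] = 0.0
        return out

    return (
        LabeledDataset(scale(train.features), train.labels.copy(), list(train.class_set), train.name),
        LabeledDataset(scale(test.features), test.labels.copy(), list(train.class_set), test.name),
    )


def load_dataset(path, name: str = None) -> LabeledDataset:
    """Read a CSV with numeric feature columns and a final ``label`` column."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty dataset file")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    feature_cols = [c for c in df.columns if c != "label"]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns")
    features = df[feature_cols]
    if df[feature_cols].isna().any().any() or df["label"].isna().any():
        raise ValueError(f"{path}: missing values are not supported")
    try:
        features = features.astype(float).to_numpy()
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric feature cell: {err}") from err
    labels = df["label"].to_numpy()
    return LabeledDataset(features, labels, name=name or str(path))


def save_dataset(dataset: LabeledDataset, path) -> None:
    """Write the CSV dialect read back by :func:`load_dataset`."""
    df = pd.DataFrame(
        dataset.features, columns=[f"f{j + 1}" for j in range(dataset.d)]
    )
    df["label"] = dataset.labels
    df.to_csv(path, index=False)
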