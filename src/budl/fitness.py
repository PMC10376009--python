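"""SVM-based fitness for wrapper feature selection.

A candidate feature subset (a binary mask over the columns of a feature
table) is scored by training a linear multiclass SVM on the masked training
split and measuring holdout accuracy, then blending accuracy and subset size
into a single minimization objective:

    M = phi * (1 - Accuracy) + gamma * n_selected / n_total

with default weights phi = 0.99 and gamma = 0.01, so accuracy dominates and
the feature-ratio term breaks ties toward smaller subsets.  With
phi + gamma = 1 the cost lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .extraction import FeatureTable

__all__ = [
    "CostConfig",
    "SVMSettings",
    "HoldoutSplit",
    "FitnessResult",
    "stratified_holdout",
    "eq1_cost",
    "evaluate_mask",
    "make_fitness",
    "FitnessEvaluator",
]


@dataclass(frozen=True)
class CostConfig:
    """Weights of the accuracy and feature-ratio terms of the cost."""

    phi: float = 0.99
    gamma: float = 0.01

    def __post_init__(self) -> None:
        if self.phi < 0 or self.gamma < 0:
            raise ValueError("phi and gamma must be non-negative")


@dataclass(frozen=True)
class SVMSettings:
    """Classifier used inside the wrapper loop.

    Linear kernel, one-vs-one multiclass, fixed C — a deliberately plain SVM
    so a fitness evaluation is fast and deterministic.
    """

    kernel: str = "linear"
    C: float = 1.0
    cache: bool = True


@dataclass(frozen=True)
class HoldoutSplit:
    """A single stratified train/test partition of the sample index range."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        tr = set(self.train_indices.tolist())
        te = set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class FitnessResult:
    """Outcome of scoring one feature mask."""

    cost: float
    accuracy: float
    n_selected: int
    n_total: int


def stratified_holdout(labels, test_fraction: float = 0.2, seed: int = 0) -> HoldoutSplit:
    """Partition samples into train/test, stratified by class.

    Per class, ``round(count * test_fraction)`` samples go to the test side
    (half-counts round up, i.e. toward the larger test set), except that at
    least one training sample per class is always retained.  The assignment
    is a seeded permutation, so the split is reproducible.

    Raises
    ------
    ValueError
        If any class has fewer than 2 samples or ``test_fraction`` is not in
        (0, 1).
    """
    labels = np.asarray(labels, dtype=object)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_test = int(np.floor(idx.size * test_fraction + 0.5))
        n_test = min(n_test, idx.size - 1)  # never empty the training side
        perm = rng.permutation(idx)
        test.extend(perm[:n_test].tolist())
        train.extend(perm[n_test:].tolist())
    return HoldoutSplit(
        train_indices=np.sort(np.array(train, dtype=int)),
        test_indices=np.sort(np.array(test, dtype=int)),
        test_fraction=test_fraction,
        seed=seed,
    )


def eq1_cost(accuracy: float, n_selected: int, n_total: int, config: CostConfig = CostConfig()) -> float:
    """Blend holdout accuracy and subset size into the scalar cost M."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if n_selected <= 0:
        raise ValueError("n_selected must be positive (empty subsets are repaired upstream)")
    if n_selected > n_total:
        raise ValueError("n_selected cannot exceed n_total")
    return config.phi * (1.0 - accuracy) + config.gamma * (n_selected / n_total)


def evaluate_mask(
    table: FeatureTable,
    split: HoldoutSplit,
    mask,
    config: CostConfig = CostConfig(),
    svm_settings: SVMSettings = SVMSettings(),
) -> FitnessResult:
    """Score one binary feature mask.

    Masked columns are standardized with statistics of the training split
    (constant columns standardize to zeros), a linear one-vs-one SVM is
    fitted on the masked training rows, and accuracy is the fraction of
    correctly labelled holdout rows.  Fully deterministic for fixed inputs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != table.n_features:
        raise ValueError("mask length must equal the number of features")
    n_selected = int(mask.sum())
    if n_selected == 0:
        raise ValueError("empty subset: mask selects no features")

    X = table.matrix[:, mask]
    y = table.labels
    Xtr, ytr = X[split.train_indices], y[split.train_indices]
    Xte, yte = X[split.test_indices], y[split.test_indices]

    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0.0] = 1.0  # constant columns -> standardized to zeros
    Xtr = (Xtr - mean) / sd
    Xte = (Xte - mean) / sd

    clf = SVC(kernel=svm_settings.kernel, C=svm_settings.C, decision_function_shape="ovo")
    clf.fit(Xtr, ytr.astype(str))
    accuracy = float(np.mean(clf.predict(Xte) == yte.astype(str)))
    return FitnessResult(
        cost=eq1_cost(accuracy, n_selected, table.n_features, config),
        accuracy=accuracy,
        n_selected=n_selected,
        n_total=table.n_features,
    )


class FitnessEvaluator:
    """Callable mapping a binary mask to a :class:`FitnessResult`.

    Results are cached keyed on the mask bits (the wrapper loop revisits
    masks often, and a cache hit skips the SVM fit without changing any
    result).  ``n_fits`` counts actual SVM fits for cache observability.
    """

    def __init__(
        self,
        table: FeatureTable,
        split: HoldoutSplit,
        config: CostConfig = CostConfig(),
        svm_settings: SVMSettings = SVMSettings(),
    ):
        max_idx = max(split.train_indices.max(), split.test_indices.max())
        if max_idx >= table.n_samples:
            raise ValueError("split indices exceed table size")
        self.table = table
        self.split = split
        self.config = config
        self.svm_settings = svm_settings
        self.n_features = table.n_features
        self.n_fits = 0
        self.n_calls = 0
        self._cache: dict[bytes, FitnessResult] = {}

    def __call__(self, mask) -> FitnessResult:
        self.n_calls += 1
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        if self.svm_settings.cache and key in self._cache:
            return self._cache[key]
        self.n_fits += 1
        result = evaluate_mask(self.table, self.split, mask, self.config, self.svm_settings)
        if self.svm_settings.cache:
            self._cache[key] = result
        return result


def make_fitness(
    table: FeatureTable,
    split: HoldoutSplit,
    config: CostConfig = CostConfig(),
    svm_settings: SVMSettings = SVMSettings(),
) -> FitnessEvaluator:
    """Bind a feature table and split into a cached mask-fitness callable."""
    return FitnessEvaluator(table, split, config, svm_settings)
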