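"""Desk-scale synthetic inputs with known ground truth.

Stands in for real ultrasound-derived deep-feature tables so the wrapper
pipeline is testable without downloads: feature tables with planted
informative columns, toy grayscale "lesion" images in a folder-per-class
layout, and analytic benchmark functions for the optimizers' raw-continuous
test mode.

The feature generator draws class-conditional Gaussians: on each of the
``k_informative`` columns, class j has mean ``j * separation`` (unit SD), so
``separation`` is the between-class mean shift in SD units; the remaining
columns are class-independent noise.  This makes expected separability
analytically predictable while the planted truth mask provides an exact
recall target for selection quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .extraction import FeatureTable

__all__ = [
    "SyntheticSpec",
    "make_synthetic_features",
    "make_synthetic_images",
    "benchmark_function",
    "BenchmarkFunction",
]

_THREE_CLASS_NAMES = ("benign", "malignant", "normal")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-feature synthetic table."""

    n_per_class: tuple[int, ...] = (50, 50, 50)
    d_total: int = 200
    k_informative: int = 10
    separation: float = 2.0
    noise_sd: float = 1.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.d_total:
            raise ValueError("k_informative cannot exceed d_total")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        if any(n < 2 for n in self.n_per_class):
            raise ValueError("every class needs at least 2 samples")


def make_synthetic_features(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Generate a labelled feature table with planted informative columns.

    Returns the table and a boolean truth mask marking the ``k_informative``
    columns (placed at a seeded random subset of positions).  With
    ``label_noise`` > 0 that fraction of labels is reassigned to a uniformly
    chosen *different* class, emulating annotation error and capping the
    attainable accuracy at a level fixed by the fixture rather than by
    holdout sampling.  Output is fully determined by the spec (including its
    seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.n_per_class)
    n_total = sum(spec.n_per_class)
    if n_classes == 3:
        class_names = _THREE_CLASS_NAMES
    else:
        class_names = tuple(f"class{j}" for j in range(n_classes))

    matrix = rng.normal(0.0, spec.noise_sd, size=(n_total, spec.d_total))
    informative = rng.choice(spec.d_total, size=spec.k_informative, replace=False)
    truth = np.zeros(spec.d_total, dtype=bool)
    truth[informative] = True

    labels = np.empty(n_total, dtype=object)
    row = 0
    for j, (name, n) in enumerate(zip(class_names, spec.n_per_class)):
        labels[row : row + n] = name
        matrix[row : row + n, informative] = rng.normal(
            j * spec.separation, 1.0, size=(n, spec.k_informative)
        )
        row += n

    if spec.label_noise > 0.0:
        n_flip = int(round(spec.label_noise * n_total))
        flip_idx = rng.choice(n_total, size=n_flip, replace=False)
        for i in flip_idx:
            alternatives = [c for c in class_names if c != labels[i]]
            labels[i] = alternatives[rng.integers(len(alternatives))]

    table = FeatureTable(
        matrix=matrix,
        labels=labels,
        feature_ids=[f"synth:{j}" for j in range(spec.d_total)],
        source=f"synthetic(seed={spec.seed})",
    )
    return table, truth


# ---------------------------------------------------------------------------
# Toy lesion images
# ---------------------------------------------------------------------------


def _speckle(rng: np.random.Generator, size: int) -> np.ndarray:
    # Rayleigh speckle texture, floored at 40 so lesion fills (below 40)
    # are the only truly dark content
    base = 40.0 + rng.rayleigh(scale=55.0, size=(size, size))
    return np.clip(base, 0, 255)


def make_synthetic_images(
    counts: tuple[int, int, int],
    out_dir: str | Path,
    size: int = 96,
    seed: int = 0,
) -> Path:
    """Write toy grayscale PNGs in a benign/malignant/normal folder layout.

    "benign" images carry a smooth dark ellipse on a speckle background,
    "malignant" an irregular star-shaped blob, and "normal" speckle only.
    Byte-identical across runs for the same arguments.
    """
    if size < 64:
        raise ValueError("size must be at least 64 px")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    for cls, n in zip(_THREE_CLASS_NAMES, counts):
        cdir = out / cls
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            arr = _speckle(rng, size)
            img = Image.fromarray(arr.astype(np.uint8), mode="L")
            draw = ImageDraw.Draw(img)
            cx = int(rng.uniform(0.35, 0.65) * size)
            cy = int(rng.uniform(0.35, 0.65) * size)
            if cls == "benign":
                rx = int(rng.uniform(0.12, 0.22) * size)
                ry = int(rng.uniform(0.10, 0.18) * size)
                draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=30)
            elif cls == "malignant":
                n_spikes = int(rng.integers(6, 10))
                angles = np.sort(rng.uniform(0, 2 * np.pi, n_spikes * 2))
                radii = np.where(
                    np.arange(n_spikes * 2) % 2 == 0,
                    rng.uniform(0.18, 0.28, n_spikes * 2) * size,
                    rng.uniform(0.06, 0.12, n_spikes * 2) * size,
                )
                points = [
                    (cx + r * np.cos(a), cy + r * np.sin(a))
                    for a, r in zip(angles, radii)
                ]
                draw.polygon(points, fill=18)
            img.save(cdir / f"{cls}_{i:03d}.png")
    return out


# ---------------------------------------------------------------------------
# Analytic benchmark functions (optimizer raw-continuous test harness)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkFunction:
    """A continuous test objective on the unit box with a known optimum."""

    name: str
    fun: callable
    optimum_value: float
    optimum_at: float  # per-coordinate optimizer location within [0, 1]

    def __call__(self, x) -> float:
        return float(self.fun(np.asarray(x, dtype=float)))

    def optimum_position(self, d: int) -> np.ndarray:
        return np.full(d, self.optimum_at)


_RASTRIGIN_SHIFT = 0.375  # interior optimum, away from box faces and 0.5


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rastrigin_shifted(x: np.ndarray) -> float:
    z = 5.12 * (x - _RASTRIGIN_SHIFT)  # map box displacement onto the usual domain
    return float(np.sum(z * z - 10.0 * np.cos(2 * np.pi * z) + 10.0))


_BENCHMARKS = {
    "sphere": BenchmarkFunction("sphere", _sphere, 0.0, 0.0),
    "rastrigin-shifted": BenchmarkFunction(
        "rastrigin-shifted", _rastrigin_shifted, 0.0, _RASTRIGIN_SHIFT
    ),
}


def benchmark_function(name: str) -> BenchmarkFunction:
    """Look up an analytic benchmark objective by name."""
    try:
        return _BENCHMARKS[name]
    except KeyError:
        raise KeyError(
            f"unknown benchmark {name!r}; available: {', '.join(sorted(_BENCHMARKS))}"
        ) from None
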