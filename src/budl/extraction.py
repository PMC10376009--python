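"""Deep-feature extraction from class-labelled ultrasound images.

Images are turned into fixed-length descriptors by tapping the activation of
the layer feeding a pre-trained CNN's final classification layer (the
"penultimate" or pre-softmax activation).  The registry below pins, for each
of the 16 supported backbones, the exact feature length that layer produces;
a backend that cannot reproduce that length for a given name refuses to
extract rather than silently emitting a different dimensionality.

Two backends are provided:

* :class:`MockBackend` — a deterministic stand-in that maps image *bytes* to
  pseudo-features of the registered length via a seeded hash.  It needs no
  network weights and is the backend used throughout the test suite.
* :class:`TorchvisionBackend` — real pretrained networks via torch/torchvision
  (optional dependency); only the names torchvision can serve at the
  registered dimensionality are mapped.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "BackboneSpec",
    "ImageDataset",
    "FeatureTable",
    "list_backbones",
    "lookup_backbone",
    "load_image_dataset",
    "extract_features",
    "save_feature_table",
    "load_feature_table",
    "MockBackend",
    "TorchvisionBackend",
    "BackboneUnavailableError",
]


class BackboneUnavailableError(RuntimeError):
    """The requested backbone cannot be served by this extraction backend."""


@dataclass(frozen=True)
class BackboneSpec:
    """A pre-trained network registered for deep-feature extraction.

    Parameters
    ----------
    name:
        Registry key, one of the 16 supported backbone names.
    input_size:
        Side length in pixels of the square input the network expects.
    layer_tag:
        Identifier of the tapped activation — always the flattened activation
        feeding the final classification layer (global-pool output where the
        architecture has one).
    feature_dim:
        Length of the extracted feature vector.  Authoritative: backends must
        produce exactly this many values per image.
    """

    name: str
    input_size: int
    layer_tag: str
    feature_dim: int

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")


# Pre-softmax feature lengths of the 16 supported backbones.  These follow the
# MATLAB model zoo variants (hence e.g. ShuffleNet=544, NASNet-Mobile=1056);
# they are the dimensionalities of record and backends must match them exactly.
_REGISTRY: dict[str, BackboneSpec] = {
    spec.name: spec
    for spec in (
        BackboneSpec("DarkNet-19", 256, "avg_pool", 1000),
        BackboneSpec("DarkNet-53", 256, "avg_pool", 1024),
        BackboneSpec("DenseNet-201", 224, "avg_pool", 1920),
        BackboneSpec("EfficientNet-b0", 224, "avg_pool", 1280),
        BackboneSpec("GoogLeNet365", 224, "pool5", 1024),
        BackboneSpec("GoogLeNet", 224, "pool5", 1024),
        BackboneSpec("Inception-ResNet-v2", 299, "avg_pool", 1536),
        BackboneSpec("Inception-v3", 299, "avg_pool", 2048),
        BackboneSpec("MobileNet-v2", 224, "global_pool", 1280),
        BackboneSpec("NASNet-Mobile", 224, "global_pool", 1056),
        BackboneSpec("ResNet-101", 224, "avg_pool", 2048),
        BackboneSpec("ResNet-50", 224, "avg_pool", 2048),
        BackboneSpec("ResNet-18", 224, "avg_pool", 512),
        BackboneSpec("ShuffleNet", 224, "global_pool", 544),
        BackboneSpec("SqueezeNet", 227, "pre_softmax_pool", 1000),
        BackboneSpec("Xception", 299, "avg_pool", 2048),
    )
}


def list_backbones() -> dict[str, BackboneSpec]:
    """Return the full backbone registry (16 entries), keyed by name."""
    return dict(_REGISTRY)


def lookup_backbone(name: str) -> BackboneSpec:
    """Look up one backbone by name.

    Raises
    ------
    KeyError
        If ``name`` is not a registered backbone.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown backbone {name!r}; registered backbones: {known}") from None


# ---------------------------------------------------------------------------
# Image datasets (folder-per-class layout)
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ImageDataset:
    """Class-labelled images enumerated from a folder-per-class directory."""

    items: tuple[tuple[Path, str], ...]
    classes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.items)


def load_image_dataset(root_dir: str | Path) -> ImageDataset:
    """Enumerate a folder-per-class image directory in sorted order.

    Each immediate subdirectory of ``root_dir`` is a class; its PNG/JPEG files
    become the dataset items.  Every file is verified to decode.

    Raises
    ------
    ValueError
        If a class directory is empty or a file does not decode.
    FileNotFoundError
        If ``root_dir`` does not exist or has no class subdirectories.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class subdirectories under {root}")

    items: list[tuple[Path, str]] = []
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"empty class directory: {cdir.name!r}")
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as exc:
                raise ValueError(f"undecodable image file: {f}") from exc
            items.append((f, cdir.name))
    return ImageDataset(items=tuple(items), classes=tuple(c.name for c in class_dirs))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """A samples × features matrix with labels and per-column provenance."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix rows must match number of labels")
        if self.matrix.shape[1] != len(self.feature_ids):
            raise ValueError("matrix columns must match number of feature_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def select_columns(self, ids: Sequence[str]) -> "FeatureTable":
        """Return a sub-table containing only the named columns, in order."""
        index = {fid: j for j, fid in enumerate(self.feature_ids)}
        cols = [index[i] for i in ids]
        return FeatureTable(
            matrix=self.matrix[:, cols],
            labels=self.labels.copy(),
            feature_ids=list(ids),
            source=self.source,
        )


def extract_features(dataset: ImageDataset, spec: BackboneSpec, backend) -> FeatureTable:
    """Extract one deep-feature row per dataset item, in dataset order.

    The backend is asked for the backbone named by ``spec``; the resulting
    row length is checked against ``spec.feature_dim`` (the registry is
    authoritative) and a mismatch is a hard error.
    """
    rows = []
    for path, _label in dataset.items:
        vec = np.asarray(backend.extract(path, spec), dtype=float).ravel()
        if vec.shape[0] != spec.feature_dim:
            raise ValueError(
                f"backend produced {vec.shape[0]} features for {spec.name}, "
                f"registry requires {spec.feature_dim}"
            )
        rows.append(vec)
    matrix = np.vstack(rows)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("extracted features contain non-finite values")
    return FeatureTable(
        matrix=matrix,
        labels=np.array([label for _p, label in dataset.items], dtype=object),
        feature_ids=[f"{spec.name}:{j}" for j in range(spec.feature_dim)],
        source=f"{spec.name}/{type(backend).__name__}",
    )


class MockBackend:
    """Deterministic pseudo-feature backend keyed on image bytes.

    Each image's feature row is standard-normal noise drawn from a generator
    seeded with a hash of (image bytes, backbone name, feature length,
    backend seed), offset by coarse intensity statistics of the decoded
    image so that visually different image classes separate in feature
    space.  Output is a pure function of (image bytes, spec, seed): two
    byte-identical images always produce the same row, and any byte
    difference produces an (almost surely) different one.  Suitable for
    exercising every downstream stage without pretrained weights.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def extract(self, path: str | Path, spec: BackboneSpec) -> np.ndarray:
        data = Path(path).read_bytes()
        h = hashlib.blake2b(digest_size=8)
        h.update(data)
        h.update(spec.name.encode())
        h.update(str(spec.feature_dim).encode())
        h.update(str(self.seed).encode())
        rng = np.random.default_rng(int.from_bytes(h.digest(), "little"))
        noise = rng.standard_normal(spec.feature_dim)

        with Image.open(path) as im:
            px = np.asarray(im.convert("L"), dtype=float) / 255.0
        stats = np.array(
            [
                px.mean(),
                px.std(),
                float((px < 0.09).mean()),   # darkest content only
                float((px < 0.14).mean()),   # any lesion-dark content
                float((px < 0.25).mean()),
                float(np.quantile(px, 0.01)),
                float(np.quantile(px, 0.05)),
                float(np.abs(np.diff(px, axis=0)).mean()),
            ]
        )
        d = spec.feature_dim
        offsets = 10.0 * np.resize(stats, d)
        return noise + offsets


# torchvision models that realize a registered backbone at exactly the
# registered feature length.  Names absent here (the DarkNets, NASNet-Mobile,
# ShuffleNet@544, GoogLeNet365, Xception, Inception-ResNet-v2) have no
# torchvision variant with the matching pre-softmax width and are refused.
_TORCHVISION_MAP = {
    "ResNet-18": "resnet18",
    "ResNet-50": "resnet50",
    "ResNet-101": "resnet101",
    "DenseNet-201": "densenet201",
    "GoogLeNet": "googlenet",
    "Inception-v3": "inception_v3",
    "MobileNet-v2": "mobilenet_v2",
    "EfficientNet-b0": "efficientnet_b0",
}


class TorchvisionBackend:
    """Real pretrained-CNN extraction backend (optional torch dependency).

    Taps the flattened activation feeding the classifier head.  Grayscale
    input is replicated to three channels; preprocessing is the backbone's
    native resize plus ImageNet normalization.
    """

    def __init__(self, device: str = "cpu"):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise BackboneUnavailableError(
                "TorchvisionBackend requires torch and torchvision "
                "(install the 'realnets' extra)"
            ) from exc
        self.device = device
        self._models: dict[str, object] = {}

    def _get_model(self, spec: BackboneSpec):
        import torch
        import torchvision.models as tvm

        if spec.name not in _TORCHVISION_MAP:
            raise BackboneUnavailableError(
                f"no torchvision model realizes {spec.name!r} at "
                f"{spec.feature_dim} features"
            )
        if spec.name not in self._models:
            model = getattr(tvm, _TORCHVISION_MAP[spec.name])(weights="DEFAULT")
            model.eval()
            # strip the classifier so forward() returns the pooled activation
            if hasattr(model, "fc"):
                model.fc = torch.nn.Identity()
            elif hasattr(model, "classifier"):
                model.classifier = torch.nn.Identity()
            self._models[spec.name] = model.to(self.device)
        return self._models[spec.name]

    def extract(self, path: str | Path, spec: BackboneSpec) -> np.ndarray:
        import torch
        from torchvision import transforms

        model = self._get_model(spec)
        tfm = transforms.Compose(
            [
                transforms.Resize((spec.input_size, spec.input_size)),
                transforms.ToTensor(),
                transforms.Normalize(
                    mean=[0.485, 0.456, 0.406], std=[0.229, 0.224, 0.225]
                ),
            ]
        )
        with Image.open(path) as im:
            im = im.convert("RGB")  # replicates single-channel input
            x = tfm(im).unsqueeze(0).to(self.device)
        with torch.no_grad():
            out = model(x)
        vec = out.squeeze(0).cpu().numpy().ravel()
        if vec.shape[0] != spec.feature_dim:
            raise BackboneUnavailableError(
                f"torchvision {spec.name} produced {vec.shape[0]} features, "
                f"registry requires {spec.feature_dim}"
            )
        return vec


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV: header ``label,<feature ids...>``.

    Values are written with 17 significant digits so the round-trip preserves
    doubles exactly.
    """
    df = pd.DataFrame(table.matrix, columns=table.feature_ids)
    df.insert(0, "label", table.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def load_feature_table(path: str | Path, source: str | None = None) -> FeatureTable:
    """Read a feature table written by :func:`save_feature_table`.

    Raises
    ------
    ValueError
        With the offending line/column named, for an empty file, a missing
        ``label`` column, ragged rows, or non-numeric cells.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: no header (empty file)")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no header (empty file)") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from None
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column in header")
    feature_ids = [c for c in df.columns if c != "label"]
    if df[feature_ids].isna().any().any() or df["label"].isna().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: ragged or missing values at data row {row + 1}")
    mat = np.empty((len(df), len(feature_ids)), dtype=float)
    for j, fid in enumerate(feature_ids):
        converted = pd.to_numeric(df[fid], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value at data row {row + 1}, column {fid!r}"
            )
        mat[:, j] = converted.to_numpy()
    return FeatureTable(
        matrix=mat,
        labels=df["label"].to_numpy(dtype=object),
        feature_ids=feature_ids,
        source=source or str(path),
    )
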