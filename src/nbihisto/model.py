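"""Patch classifier contract, reference backends, and stratified 3-fold CV.

The classifier is a pluggable contract: anything with a
``predict(patches) -> categories`` method over 7 classes. The configuration
of the full-scale reference model (a ResNet50-class network trained from
scratch on 224 x 224 inputs with Adam, cross-entropy loss, 50 epochs, batch
size 256 and learning rate 5e-5) ships as :data:`REFERENCE_TRAIN_CONFIG`;
the trainable backend used throughout the test suite is a light
spectral-and-chroma feature model that runs in seconds on one CPU.

Cross-validation is stratified at the lesion level by default so that
near-duplicate frames of one lesion never straddle a train/validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image

from .types import (
    AnnotatedImage,
    ChannelError,
    InputError,
    FoldAssignment,
    PatchManifest,
    PatchRecord,
    PredictionMap,
    window,
)

N_CLASSES = 7
INPUT_SIZE = 224


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters of the patch classifier."""

    optimizer: str = "adam"
    loss: str = "cross_entropy"
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 5e-5
    n_classes: int = N_CLASSES
    input_size: int = INPUT_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must be {N_CLASSES}")
        if self.input_size != INPUT_SIZE:
            raise ValueError(f"input_size must be {INPUT_SIZE}")
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


#: The full-scale configuration of the reference residual network.
REFERENCE_TRAIN_CONFIG = TrainConfig()


@runtime_checkable
class PatchClassifier(Protocol):
    """Contract: deterministic 7-class prediction over patch rasters."""

    def predict(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        """Return one category 0-6 per input patch."""
        ...


def stratified_folds(
    units: Sequence[tuple[str, int]],
    k: int = 3,
    seed: int = 0,
    unit: str = "lesion",
) -> FoldAssignment:
    """Partition units into k folds with near-equal label proportions.

    Deterministic under a fixed seed and invariant to input ordering (units
    are sorted before shuffling). Within each label, fold counts differ by
    at most one; each label's remainder units go to the currently smallest
    folds, which also balances total fold sizes to within one unit.
    """
    units = list(units)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(units):
        raise ValueError(f"cannot partition {len(units)} units into {k} folds")
    ids = [u for u, _ in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit ids in fold input")
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[str]] = {}
    for uid, label in sorted(units):
        by_label.setdefault(label, []).append(uid)
    mapping: dict[str, int] = {}
    totals = [0] * k
    for label in sorted(by_label):
        members = by_label[label]
        if len(members) < k:
            warnings.warn(
                f"label {label} has only {len(members)} units for {k} folds; "
                "stratum is degenerate",
                stacklevel=2,
            )
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        q, r = divmod(len(shuffled), k)
        per_fold = [q] * k
        for fold in sorted(range(k), key=lambda f: (totals[f], f))[:r]:
            per_fold[fold] += 1
        pos = 0
        for fold in range(k):
            for uid in shuffled[pos : pos + per_fold[fold]]:
                mapping[uid] = fold
            totals[fold] += per_fold[fold]
            pos += per_fold[fold]
    return FoldAssignment(unit=unit, k=k, mapping=mapping, seed=seed)


def resize_patch(patch: np.ndarray, size: int = INPUT_SIZE) -> np.ndarray:
    """Bilinear resize of a 3-channel patch to size x size, clipped to [0, 255]."""
    arr = np.asarray(patch)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ChannelError(f"expected H x W x 3 patch, got {arr.shape}")
    img = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8), mode="RGB")
    out = img.resize((size, size), Image.BILINEAR)
    return np.asarray(out, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Reference backends


class OracleBackend:
    """Upper-bound backend: answers with the true category of each window.

    Decouples the aggregation stage from classifier quality — with this
    backend the patch-level accuracy is 1 for every category by construction.
    """

    def __init__(self, manifest: PatchManifest):
        self._truth = {
            (r.image_id, r.origin[0], r.origin[1]): r.category
            for r in manifest.records
        }
        self._pending: list[tuple[str, int, int]] = []

    def bind(self, keys: Sequence[tuple[str, int, int]]) -> "OracleBackend":
        self._pending = list(keys)
        return self

    def predict(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        if len(self._pending) != len(patches):
            raise InputError("oracle backend requires bound record keys")
        out = np.array([self._truth[k] for k in self._pending], dtype=int)
        self._pending = []
        return out


class ConstantBackend:
    """Predicts one fixed category for everything; a degenerate baseline."""

    def __init__(self, category: int):
        if not 0 <= category <= 6:
            raise ValueError("category outside 0-6")
        self.category = category

    def predict(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        return np.full(len(patches), self.category, dtype=int)


def patch_features(patch: np.ndarray, n_bands: int = 6) -> np.ndarray:
    """Feature vector for the light trainable backend.

    Channel means and standard deviations capture chroma and contrast;
    log-energies of ``n_bands`` radial spectral bands of the green channel
    capture the dominant texture frequency and the loss of high-frequency
    content in defocused regions.
    """
    arr = np.asarray(patch, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ChannelError(f"expected H x W x 3 patch, got {arr.shape}")
    arr = arr / 255.0
    means = arr.mean(axis=(0, 1))
    stds = arr.std(axis=(0, 1))
    green = arr[..., 1]
    spectrum = np.abs(np.fft.fft2(green)) ** 2
    fy = np.fft.fftfreq(green.shape[0])
    fx = np.fft.fftfreq(green.shape[1])
    radius = np.hypot(fy[:, None], fx[None, :])
    edges = np.geomspace(0.01, 0.5 * np.sqrt(2) + 1e-9, n_bands + 1)
    edges[0] = 1e-12  # keep non-DC low frequencies, drop only the DC bin
    bands = np.empty(n_bands)
    for i in range(n_bands):
        sel = (radius > edges[i]) & (radius <= edges[i + 1])
        bands[i] = np.log10(spectrum[sel].sum() + 1e-12)
    return np.concatenate([means, stds, bands])


class SpectralChromaBackend:
    """Trainable reference backend: logistic regression on patch features.

    A deliberately small model so the whole cross-validated pipeline runs on
    one CPU in well under a minute; the contract it fulfils is identical to
    a full-scale convolutional backend's.
    """

    def __init__(self, seed: int = 0, max_iter: int = 2000):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self.seed = seed
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=max_iter, random_state=seed),
        )
        self._fitted = False

    def fit(self, patches: Sequence[np.ndarray], categories: Sequence[int]) -> None:
        X = np.stack([patch_features(p) for p in patches])
        self._model.fit(X, np.asarray(categories, dtype=int))
        self._fitted = True

    def predict(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        if not self._fitted:
            raise InputError("backend is not trained")
        X = np.stack([patch_features(p) for p in patches])
        return self._model.predict(X).astype(int)


# ---------------------------------------------------------------------------
# Training and prediction over manifests


def extract_patch(
    image: AnnotatedImage, record: PatchRecord, input_size: int = INPUT_SIZE
) -> np.ndarray:
    """Cut the record's window from its image and resize to the model input."""
    raw = window(image.pixels, record.origin, record.size)
    return resize_patch(raw, input_size)


def _records_by_fold(
    manifest: PatchManifest, folds: FoldAssignment
) -> dict[str, int]:
    """Map each image id to its fold via the manifest's provenance."""
    out = {}
    for image_id, prov in manifest.provenance.items():
        unit_id = prov["lesion_id"] if folds.unit == "lesion" else image_id
        if unit_id not in folds.mapping:
            raise InputError(f"unit {unit_id!r} missing from fold assignment")
        out[image_id] = folds.mapping[unit_id]
    return out


def train_classifier(
    manifest: PatchManifest,
    folds: FoldAssignment,
    val_fold: int,
    images: dict[str, AnnotatedImage],
    config: TrainConfig = REFERENCE_TRAIN_CONFIG,
    backend: Optional[SpectralChromaBackend] = None,
) -> SpectralChromaBackend:
    """Fit a backend on every admitted patch outside ``val_fold``."""
    image_fold = _records_by_fold(manifest, folds)
    train_records = [
        r for r in manifest.records if image_fold[r.image_id] != val_fold
    ]
    if not train_records:
        raise InputError(f"no training patches outside fold {val_fold}")
    if backend is None:
        backend = SpectralChromaBackend(seed=config.seed)
    patches = [
        extract_patch(images[r.image_id], r, config.input_size)
        for r in train_records
    ]
    backend.fit(patches, [r.category for r in train_records])
    return backend


def predict_patches(
    classifier: PatchClassifier,
    records: Sequence[PatchRecord],
    images: dict[str, AnnotatedImage],
    input_size: int = INPUT_SIZE,
) -> PredictionMap:
    """One predicted category per record, order-preserving per image."""
    for r in records:
        if r.image_id not in images:
            raise InputError(f"image {r.image_id!r} not available for prediction")
    if not records:
        return {}
    if isinstance(classifier, OracleBackend):
        classifier.bind([(r.image_id, r.origin[0], r.origin[1]) for r in records])
        categories = classifier.predict([None] * len(records))
    else:
        patches = [extract_patch(images[r.image_id], r, input_size) for r in records]
        categories = classifier.predict(patches)
    out: PredictionMap = {}
    for record, category in zip(records, categories):
        out.setdefault(record.image_id, []).append(
            (record.origin[0], record.origin[1], int(category))
        )
    return out
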