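"""Core domain containers shared across the pipeline.

The unit of image-level classification is an :class:`AnnotatedImage` — an RGB
still with a binary lesion annotation mask, a lesion-level histology label and
an optional effective region of interest. Patches cut from it on a strided
grid become :class:`PatchRecord` rows; a trained classifier turns them into a
:class:`PredictionMap`, which the aggregation stage reduces back to a single
histology call per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Category codes used throughout. 0-4 are in-focus classes (background plus
#: the four histologic grades); 5 and 6 are their out-of-focus counterparts.
CATEGORY_NAMES = ("BG", "LGD", "HGD", "SMs", "SMd", "BG-oof", "L-oof")
#: Histology labels valid for a lesion annotation.
LESION_LABELS = (1, 2, 3, 4)
#: Labels that participate in union masks and the image-level argmax.
IN_FOCUS_LABELS = (0, 1, 2, 3, 4)


class ShapeError(ValueError):
    """Raster dimensions do not match what the operation requires."""


class ChannelError(ValueError):
    """Image does not carry the expected number of color channels."""


class ConfigurationError(ValueError):
    """A required configuration value is missing or inconsistent."""


class InputError(ValueError):
    """A dataset input (image, mask, manifest row) is missing or malformed."""


class UndefinedFractionError(ZeroDivisionError):
    """A quality fraction has an empty denominator (no usable window pixels)."""


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


@dataclass(frozen=True)
class QualityMasks:
    """Blackout, halation and effective-region masks for one image.

    ``effective`` is the usable area: the ROI (full frame when absent) minus
    blacked-out and halated pixels. Invariants are enforced on construction.
    """

    blackout: np.ndarray
    halation: np.ndarray
    effective: np.ndarray

    def __post_init__(self) -> None:
        b, h, e = (_as_bool(m) for m in (self.blackout, self.halation, self.effective))
        if not (b.shape == h.shape == e.shape):
            raise ShapeError(
                f"quality masks disagree on shape: {b.shape}, {h.shape}, {e.shape}"
            )
        if (e & b).any() or (e & h).any():
            raise ValueError("effective region overlaps blackout or halation")
        object.__setattr__(self, "blackout", b)
        object.__setattr__(self, "halation", h)
        object.__setattr__(self, "effective", e)

    @property
    def shape(self) -> tuple[int, int]:
        return self.effective.shape


@dataclass(frozen=True)
class FocusScore:
    """High-frequency spectral energy fraction of a patch.

    ``value`` is the share of non-DC spectral energy above ``cutoff`` (a
    fraction of the Nyquist frequency). ``threshold`` is the in-focus
    decision bound; it may be left unset and supplied by configuration.
    """

    value: float
    cutoff: float = 0.0625
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"focus value {self.value} outside [0, 1]")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff {self.cutoff} outside (0, 1)")


@dataclass(frozen=True)
class AnnotatedImage:
    """An RGB still, its lesion mask, the lesion-level label and optional ROI."""

    image_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    lesion_mask: np.ndarray  # H x W bool
    label: int  # 1=LGD, 2=HGD, 3=SMs, 4=SMd
    lesion_id: Optional[str] = None
    roi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ChannelError(f"expected H x W x 3 RGB raster, got {px.shape}")
        mask = _as_bool(self.lesion_mask)
        if mask.shape != px.shape[:2]:
            raise ShapeError(
                f"lesion mask {mask.shape} does not match image {px.shape[:2]}"
            )
        if self.label not in LESION_LABELS:
            raise ValueError(f"lesion label {self.label} not in {LESION_LABELS}")
        roi = self.roi
        if roi is not None:
            roi = _as_bool(roi)
            if roi.shape != px.shape[:2]:
                raise ShapeError(f"ROI {roi.shape} does not match image {px.shape[:2]}")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))
        object.__setattr__(self, "lesion_mask", mask)
        object.__setattr__(self, "roi", roi)
        if self.lesion_id is None:
            object.__setattr__(self, "lesion_id", self.image_id)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PatchRecord:
    """One admitted grid window and everything known about it."""

    image_id: str
    origin: tuple[int, int]  # (row, col), 0-based top-left
    size: int
    blackout_fraction: float
    halation_fraction: float
    focus_value: float
    category: int  # 0-6

    def __post_init__(self) -> None:
        if not 0 <= self.category <= 6:
            raise ValueError(f"category {self.category} outside 0-6")
        for name in ("blackout_fraction", "halation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class PatchManifest:
    """All admitted patches of a dataset plus per-image provenance."""

    records: list[PatchRecord]
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def counts(self) -> dict[int, int]:
        out = {c: 0 for c in range(7)}
        for r in self.records:
            out[r.category] += 1
        return out

    def for_image(self, image_id: str) -> list[PatchRecord]:
        return [r for r in self.records if r.image_id == image_id]


#: Per-image patch predictions: image_id -> list of (row, col, category),
#: in the order of the records that produced them.
PredictionMap = dict[str, list[tuple[int, int, int]]]


@dataclass(frozen=True)
class MaskSet:
    """The effective annotation mask X and the per-label union masks M0-M4."""

    X: np.ndarray
    M: tuple[np.ndarray, ...]  # five rasters indexed by label 0-4

    def __post_init__(self) -> None:
        if len(self.M) != 5:
            raise ValueError("MaskSet requires exactly five union masks M0-M4")
        for m in self.M:
            if m.shape != self.X.shape:
                raise ShapeError("union mask shape differs from annotation mask")


@dataclass(frozen=True)
class IoUVector:
    """IoU of X against each of M0-M4 and the winning label."""

    iou: tuple[float, float, float, float, float]
    argmax_label: int

    def __post_init__(self) -> None:
        for v in self.iou:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"IoU {v} outside [0, 1]")
        if self.iou[self.argmax_label] != max(self.iou):
            raise ValueError("argmax_label does not attain the maximum IoU")


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified k-fold partition of cross-validation units."""

    unit: str  # "lesion", "image" or "patch"
    k: int
    mapping: dict[str, int]
    seed: int

    def fold_of(self, unit_id: str) -> int:
        return self.mapping[unit_id]

    def units_in(self, fold: int) -> list[str]:
        return sorted(u for u, f in self.mapping.items() if f == fold)


def ensure_rgb(image: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit H x W x 3 array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ChannelError(f"expected a 3-channel RGB raster, got shape {arr.shape}")
    return arr


def window(arr: np.ndarray, origin: Sequence[int], size: int) -> np.ndarray:
    """The half-open size x size view of ``arr`` at (row, col) ``origin``."""
    r, c = origin
    if r < 0 or c < 0 or r + size > arr.shape[0] or c + size > arr.shape[1]:
        raise ShapeError(
            f"window at {origin} of size {size} exceeds raster {arr.shape[:2]}"
        )
    return arr[r : r + size, c : c + size]
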