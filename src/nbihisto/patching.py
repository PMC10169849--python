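"""Strided patch grid, admission rules and category assignment.

Patches of 128 x 128 px are cut on a 32 px stride in raster order
(left-to-right, then top-to-bottom). A window is admitted when at most 10%
of its usable area is blacked out and at most 5% halated (exclusion is
strict: "more than" / "exceeding"). Admitted windows receive one of seven
training categories: in-focus background (0), the four histologic grades
(1-4), and out-of-focus background (5) or lesion (6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from . import quality
from .types import (
    AnnotatedImage,
    InputError,
    PatchManifest,
    PatchRecord,
    QualityMasks,
    ShapeError,
    UndefinedFractionError,
    window,
)

PATCH_SIZE = 128
STRIDE = 32
BLACKOUT_MAX_FRACTION = 0.10
HALATION_MAX_FRACTION = 0.05
COVERAGE_THRESHOLD = 0.5


@dataclass(frozen=True)
class PatchingConfig:
    """Constants governing patch extraction and labeling."""

    patch_size: int = PATCH_SIZE
    stride: int = STRIDE
    blackout_max: float = BLACKOUT_MAX_FRACTION
    halation_max: float = HALATION_MAX_FRACTION
    focus_cutoff: float = quality.DEFAULT_CUTOFF
    focus_threshold: float = quality.DEFAULT_FOCUS_THRESHOLD
    focus_channel: int = quality.DEFAULT_FOCUS_CHANNEL
    coverage_threshold: float = COVERAGE_THRESHOLD


def grid_origins(
    width: int, height: int, patch: int = PATCH_SIZE, stride: int = STRIDE
) -> list[tuple[int, int]]:
    """Top-left origins of the strided grid, in raster scan order.

    Counts floor((dim - patch)/stride) + 1 positions per axis; an image
    smaller than the patch in either dimension yields no origins.
    """
    if patch < 1 or stride < 1:
        raise ValueError("patch and stride must be positive")
    if height < patch or width < patch:
        return []
    rows = range(0, height - patch + 1, stride)
    cols = range(0, width - patch + 1, stride)
    return [(r, c) for r in rows for c in cols]


def patch_fractions(
    origin: tuple[int, int],
    masks: QualityMasks,
    patch: int = PATCH_SIZE,
    roi: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Blackout and halation fractions of one window.

    The denominator is the window's overlap with the ROI (the full window
    when none is given) so border windows are judged on their usable area.
    """
    black = window(masks.blackout, origin, patch)
    hal = window(masks.halation, origin, patch)
    if roi is None:
        denom = patch * patch
        black_n = int(black.sum())
        hal_n = int(hal.sum())
    else:
        roi_w = window(np.asarray(roi, dtype=bool), origin, patch)
        denom = int(roi_w.sum())
        if denom == 0:
            raise UndefinedFractionError(
                f"window at {origin} has no ROI overlap; fractions undefined"
            )
        black_n = int((black & roi_w).sum())
        hal_n = int((hal & roi_w).sum())
    return black_n / denom, hal_n / denom


def admit_patch(
    fractions: tuple[float, float],
    blackout_max: float = BLACKOUT_MAX_FRACTION,
    halation_max: float = HALATION_MAX_FRACTION,
) -> bool:
    """True iff neither quality fraction exceeds its bound (bounds pass)."""
    blackout_fraction, halation_fraction = fractions
    return blackout_fraction <= blackout_max and halation_fraction <= halation_max


def assign_category(
    origin: tuple[int, int],
    lesion_mask: np.ndarray,
    in_focus: bool,
    lesion_label: int,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    effective: Optional[np.ndarray] = None,
    patch: int = PATCH_SIZE,
) -> int:
    """Assign one of the seven training categories to a window.

    Lesion membership is decided by the lesion mask's coverage of the
    window's effective pixels (the whole window when ``effective`` is None):
    in-focus lesion -> the image's histology label, in-focus background -> 0,
    out-of-focus lesion -> 6, out-of-focus background -> 5.
    """
    if lesion_label not in (1, 2, 3, 4):
        raise ValueError(f"lesion label {lesion_label} not in 1-4")
    lesion_w = window(np.asarray(lesion_mask, dtype=bool), origin, patch)
    if effective is None:
        denom = patch * patch
        covered = int(lesion_w.sum())
    else:
        eff_w = window(np.asarray(effective, dtype=bool), origin, patch)
        denom = int(eff_w.sum())
        if denom == 0:
            raise UndefinedFractionError(
                f"window at {origin} has no effective pixels; coverage undefined"
            )
        covered = int((lesion_w & eff_w).sum())
    is_lesion = covered / denom >= coverage_threshold
    if in_focus:
        return lesion_label if is_lesion else 0
    return 6 if is_lesion else 5


def patches_for_image(
    image: AnnotatedImage,
    config: PatchingConfig = PatchingConfig(),
    masks: Optional[QualityMasks] = None,
) -> list[PatchRecord]:
    """All admitted, categorized patch records of one image.

    Windows with zero ROI overlap are skipped silently; windows failing the
    blackout/halation admission rule are dropped.
    """
    if masks is None:
        masks = quality.effective_mask(image.pixels, image.roi)
    if masks.shape != image.shape:
        raise ShapeError("quality masks do not match image dimensions")
    records: list[PatchRecord] = []
    gray = image.pixels[..., config.focus_channel]
    for origin in grid_origins(
        image.shape[1], image.shape[0], config.patch_size, config.stride
    ):
        try:
            fractions = patch_fractions(origin, masks, config.patch_size, image.roi)
        except UndefinedFractionError:
            continue
        if not admit_patch(fractions, config.blackout_max, config.halation_max):
            continue
        score = quality.focus_score(
            window(gray, origin, config.patch_size), config.focus_cutoff
        )
        eff_w = window(masks.effective, origin, config.patch_size)
        if not eff_w.any():
            continue  # fully blacked-out/halated yet admitted windows carry no label
        category = assign_category(
            origin,
            image.lesion_mask,
            quality.is_in_focus(score, config.focus_threshold),
            image.label,
            config.coverage_threshold,
            effective=masks.effective,
            patch=config.patch_size,
        )
        records.append(
            PatchRecord(
                image_id=image.image_id,
                origin=origin,
                size=config.patch_size,
                blackout_fraction=fractions[0],
                halation_fraction=fractions[1],
                focus_value=score.value,
                category=category,
            )
        )
    return records


def build_manifest(
    images: Iterable[AnnotatedImage], config: PatchingConfig = PatchingConfig()
) -> PatchManifest:
    """One record per admitted grid window per image; deterministic."""
    records: list[PatchRecord] = []
    provenance: dict[str, dict] = {}
    for image in images:
        if image.lesion_mask is None:
            raise InputError(f"image {image.image_id} has no lesion mask")
        records.extend(patches_for_image(image, config))
        provenance[image.image_id] = {
            "label": image.label,
            "lesion_id": image.lesion_id,
        }
    return PatchManifest(records=records, provenance=provenance)
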