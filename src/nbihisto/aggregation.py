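"""Image-level classification by union-mask IoU argmax.

For one image, the footprints of all patches predicted as in-focus label i
(0=BG through 4=SMd) are unioned into mask Mi and intersected with the
effective region; out-of-focus predictions (categories 5, 6) contribute to
no union mask. The effective annotation mask X (lesion annotation minus
blackout and halation) is compared with each Mi by intersection-over-union,
and the image is called as the argmax over IoU_0..IoU_4, with ties broken
toward the more severe label. An argmax of 0 is a background/no-lesion call.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    AnnotatedImage,
    InputError,
    IoUVector,
    MaskSet,
    PredictionMap,
    QualityMasks,
    ShapeError,
)

PATCH_SIZE = 128


def union_mask(
    predictions: Sequence[tuple[int, int, int]],
    label: int,
    masks: QualityMasks,
    patch_size: int = PATCH_SIZE,
) -> np.ndarray:
    """Union of footprints of patches predicted as ``label``, inside the
    effective region.

    ``predictions`` is one image's list of (row, col, category). Overlapping
    footprints (stride < patch size) are counted once by construction.
    """
    if not 0 <= label <= 4:
        raise ValueError(f"union masks exist only for labels 0-4, got {label}")
    out = np.zeros(masks.shape, dtype=bool)
    for row, col, category in predictions:
        if category != label:
            continue
        if row < 0 or col < 0 or row + patch_size > out.shape[0] or col + patch_size > out.shape[1]:
            raise ShapeError(f"predicted window at ({row}, {col}) exceeds frame")
        out[row : row + patch_size, col : col + patch_size] = True
    return out & masks.effective


def iou(x: np.ndarray, m: np.ndarray) -> float:
    """|X ∩ M| / |X ∪ M|; defined as 0 when both masks are empty."""
    a = np.asarray(x, dtype=bool)
    b = np.asarray(m, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def classify_image(iou_values: Sequence[float]) -> int:
    """Index of the maximum IoU; ties broken toward the larger label index."""
    values = np.asarray(iou_values, dtype=float)
    if values.size == 0 or not np.isfinite(values).all():
        raise ValueError(f"IoU vector must be finite and nonempty, got {iou_values}")
    # argmax of the reversed vector keeps the last (most severe) maximum
    return int(values.size - 1 - np.argmax(values[::-1]))


def mask_set(
    image: AnnotatedImage,
    predictions: Sequence[tuple[int, int, int]],
    masks: QualityMasks,
    patch_size: int = PATCH_SIZE,
) -> MaskSet:
    """Build X and M0-M4 for one image."""
    if image.lesion_mask is None:
        raise InputError(f"image {image.image_id} has no annotation mask")
    if masks.shape != image.shape:
        raise ShapeError("quality masks do not match image dimensions")
    x = image.lesion_mask & masks.effective
    m = tuple(
        union_mask(predictions, label, masks, patch_size) for label in range(5)
    )
    return MaskSet(X=x, M=m)


def aggregate(
    image: AnnotatedImage,
    predictions: PredictionMap,
    masks: Optional[QualityMasks] = None,
    patch_size: int = PATCH_SIZE,
) -> tuple[IoUVector, int]:
    """Full image-level call: union masks, the five IoUs, and the argmax."""
    from . import quality  # local import to avoid a cycle at module load

    if masks is None:
        masks = quality.effective_mask(image.pixels, image.roi)
    preds = predictions.get(image.image_id, [])
    ms = mask_set(image, preds, masks, patch_size)
    values = tuple(iou(ms.X, mi) for mi in ms.M)
    label = classify_image(values)
    return IoUVector(iou=values, argmax_label=label), label
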