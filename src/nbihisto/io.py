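"""Dataset layout and file-format conventions.

A dataset directory holds ``images/<id>.png`` (RGB stills; TIFF and JPEG
are also accepted), ``masks/<id>.png`` (binary lesion annotations, 0 =
background, 255 = lesion), optional ``roi/<id>.png``, and ``labels.csv``
with columns ``image_id, lesion_id, label``. Patch manifests are CSV with a
JSON sidecar echoing the configuration; predictions and audit records are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from PIL import Image

from .patching import PatchingConfig
from .types import AnnotatedImage, InputError, PatchManifest, PatchRecord, PredictionMap

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
MANIFEST_COLUMNS = [
    "image_id",
    "row",
    "col",
    "blackout_fraction",
    "halation_fraction",
    "focus_value",
    "category",
]


def read_mask(path: Path) -> np.ndarray:
    """Single-channel PNG to bool: 0 = false, anything else = true."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0


def write_mask(path: Path, mask: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(
        path
    )


def read_image(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path: Path, pixels: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def _find_image(directory: Path, image_id: str) -> Path:
    for ext in IMAGE_EXTENSIONS:
        candidate = directory / f"{image_id}{ext}"
        if candidate.exists():
            return candidate
    raise InputError(f"no image file for {image_id!r} under {directory}")


def load_dataset(dataset_dir: Path | str) -> list[AnnotatedImage]:
    """Read the standard layout into a list of annotated images."""
    root = Path(dataset_dir)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise InputError(f"missing labels file: {labels_path}")
    table = pd.read_csv(labels_path, dtype={"image_id": str, "lesion_id": str})
    for column in ("image_id", "lesion_id", "label"):
        if column not in table.columns:
            raise InputError(f"labels.csv lacks required column {column!r}")
    images: list[AnnotatedImage] = []
    for row in table.itertuples(index=False):
        image_path = _find_image(root / "images", row.image_id)
        mask_path = root / "masks" / f"{row.image_id}.png"
        if not mask_path.exists():
            raise InputError(f"missing annotation mask: {mask_path}")
        roi_path = root / "roi" / f"{row.image_id}.png"
        images.append(
            AnnotatedImage(
                image_id=row.image_id,
                pixels=read_image(image_path),
                lesion_mask=read_mask(mask_path),
                label=int(row.label),
                lesion_id=row.lesion_id,
                roi=read_mask(roi_path) if roi_path.exists() else None,
            )
        )
    if not images:
        raise InputError(f"dataset at {root} lists no images")
    return images


def write_dataset(dataset_dir: Path | str, images: Iterable[AnnotatedImage]) -> None:
    root = Path(dataset_dir)
    rows = []
    for image in images:
        write_image(root / "images" / f"{image.image_id}.png", image.pixels)
        write_mask(root / "masks" / f"{image.image_id}.png", image.lesion_mask)
        if image.roi is not None:
            write_mask(root / "roi" / f"{image.image_id}.png", image.roi)
        rows.append(
            {
                "image_id": image.image_id,
                "lesion_id": image.lesion_id,
                "label": image.label,
            }
        )
    root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(root / "labels.csv", index=False)


def write_manifest(
    path: Path | str,
    manifest: PatchManifest,
    config: Optional[PatchingConfig] = None,
) -> None:
    """Manifest as CSV plus a JSON sidecar echoing config and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "row": r.origin[0],
                "col": r.origin[1],
                "blackout_fraction": r.blackout_fraction,
                "halation_fraction": r.halation_fraction,
                "focus_value": r.focus_value,
                "category": r.category,
            }
            for r in manifest.records
        ],
        columns=MANIFEST_COLUMNS,
    )
    frame.to_csv(path, index=False)
    sidecar = {
        "config": vars(config) if config is not None else None,
        "provenance": manifest.provenance,
        "counts": {str(k): v for k, v in manifest.counts.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_manifest(path: Path | str, patch_size: int = 128) -> PatchManifest:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"image_id": str})
    records = [
        PatchRecord(
            image_id=r.image_id,
            origin=(int(r.row), int(r.col)),
            size=patch_size,
            blackout_fraction=float(r.blackout_fraction),
            halation_fraction=float(r.halation_fraction),
            focus_value=float(r.focus_value),
            category=int(r.category),
        )
        for r in frame.itertuples(index=False)
    ]
    provenance = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", {})
    return PatchManifest(records=records, provenance=provenance)


def write_predictions(path: Path | str, predictions: PredictionMap) -> None:
    payload = {
        image_id: [
            {"row": row, "col": col, "category": category}
            for row, col, category in entries
        ]
        for image_id, entries in predictions.items()
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_predictions(path: Path | str) -> PredictionMap:
    payload = json.loads(Path(path).read_text())
    return {
        image_id: [(e["row"], e["col"], e["category"]) for e in entries]
        for image_id, entries in payload.items()
    }
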