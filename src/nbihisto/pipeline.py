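"""End-to-end cross-validated pipeline.

``run_pipeline`` chains manifest building, stratified fold assignment,
per-fold training and prediction, per-image union-mask aggregation and the
final metrics. Every record is predicted exactly once, by the model whose
training split excluded it; the merged predictions drive the image-level
confusion matrix.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import aggregation, io, model, quality
from .config import PipelineConfig
from .metrics import ConfusionMatrix, FoldReport, confusion
from .types import (
    AnnotatedImage,
    CATEGORY_NAMES,
    ConfigurationError,
    InputError,
    PatchManifest,
    PatchRecord,
    PredictionMap,
)
from .patching import build_manifest

log = logging.getLogger("nbihisto")

IMAGE_CLASS_NAMES = ("BG", "LGD", "HGD", "SMs", "SMd")


@dataclass
class ImageAudit:
    """Per-image audit record of the aggregation stage."""

    image_id: str
    iou: list[float]
    label: int
    truth: int

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "iou": self.iou,
            "label": self.label,
            "truth": self.truth,
        }


@dataclass
class PipelineResult:
    report: FoldReport
    audits: list[ImageAudit]
    predictions: PredictionMap
    manifest: PatchManifest

    @property
    def image_level_accuracy(self) -> float:
        if not self.audits:
            raise InputError("no images were aggregated")
        correct = sum(1 for a in self.audits if a.label == a.truth)
        return correct / len(self.audits)


def _record_unit(record: PatchRecord, manifest: PatchManifest, unit: str) -> str:
    prov = manifest.provenance[record.image_id]
    if unit == "lesion":
        return str(prov["lesion_id"])
    if unit == "image":
        return record.image_id
    if unit == "patch":
        return f"{record.image_id}:{record.origin[0]}:{record.origin[1]}"
    raise ConfigurationError(f"unknown CV unit {unit!r}")


def _cv_units(manifest: PatchManifest, unit: str) -> list[tuple[str, int]]:
    if unit == "patch":
        return [
            (_record_unit(r, manifest, unit), r.category) for r in manifest.records
        ]
    seen: dict[str, int] = {}
    for image_id, prov in manifest.provenance.items():
        uid = str(prov["lesion_id"]) if unit == "lesion" else image_id
        seen[uid] = int(prov["label"])
    return sorted(seen.items())


def make_backend(name: str, manifest: PatchManifest, seed: int = 0):
    """Instantiate a classifier backend from its config name."""
    if name == "oracle":
        return model.OracleBackend(manifest)
    if name == "spectral":
        return model.SpectralChromaBackend(seed=seed)
    if name.startswith("constant:"):
        return model.ConstantBackend(int(name.split(":", 1)[1]))
    raise ConfigurationError(f"unknown backend {name!r}")


def cross_validate(
    images: Sequence[AnnotatedImage],
    config: PipelineConfig = PipelineConfig(),
    manifest: Optional[PatchManifest] = None,
) -> PipelineResult:
    """Three-fold (by default) cross-validation of the full pipeline."""
    images = list(images)
    if not images:
        raise InputError("no input images")
    image_index = {im.image_id: im for im in images}
    if manifest is None:
        manifest = build_manifest(images, config.patching())
    units = _cv_units(manifest, config.cv.unit)
    folds = model.stratified_folds(
        units, k=config.cv.k, seed=config.cv.seed, unit=config.cv.unit
    )

    report = FoldReport(
        per_category={name: [] for name in CATEGORY_NAMES}
    )
    merged: PredictionMap = {}
    for fold in range(folds.k):
        val_records = [
            r
            for r in manifest.records
            if folds.mapping[_record_unit(r, manifest, config.cv.unit)] == fold
        ]
        train_records = [
            r
            for r in manifest.records
            if folds.mapping[_record_unit(r, manifest, config.cv.unit)] != fold
        ]
        if not train_records or not val_records:
            raise InputError(f"fold {fold} leaves an empty train or validation split")
        backend = make_backend(config.backend, manifest, seed=config.train.seed)
        if isinstance(backend, model.SpectralChromaBackend):
            patches = [
                model.extract_patch(
                    image_index[r.image_id], r, config.train.input_size
                )
                for r in train_records
            ]
            backend.fit(patches, [r.category for r in train_records])
        predictions = model.predict_patches(
            backend, val_records, image_index, config.train.input_size
        )
        log.info(
            "fold %d: %d train / %d validation patches",
            fold,
            len(train_records),
            len(val_records),
        )
        predicted_of = {
            (image_id, row, col): category
            for image_id, entries in predictions.items()
            for row, col, category in entries
        }
        for cat, name in enumerate(CATEGORY_NAMES):
            cat_records = [r for r in val_records if r.category == cat]
            if not cat_records:
                continue
            correct = sum(
                1
                for r in cat_records
                if predicted_of[(r.image_id, r.origin[0], r.origin[1])] == cat
            )
            report.per_category[name].append(
                (len(cat_records), correct, correct / len(cat_records))
            )
        for image_id, entries in predictions.items():
            merged.setdefault(image_id, []).extend(entries)

    report.per_category = {
        name: triplets for name, triplets in report.per_category.items() if triplets
    }

    audits: list[ImageAudit] = []
    truths, calls = [], []
    for image in images:
        if image.image_id not in merged and not manifest.for_image(image.image_id):
            continue  # image contributed no admissible patches
        masks = quality.effective_mask(image.pixels, image.roi)
        vector, label = aggregation.aggregate(
            image, merged, masks, config.patch_size
        )
        audits.append(
            ImageAudit(
                image_id=image.image_id,
                iou=list(vector.iou),
                label=label,
                truth=image.label,
            )
        )
        truths.append(image.label)
        calls.append(label)
    if truths:
        report.image_level = confusion(truths, calls, classes=list(range(5)))
        report.image_level = ConfusionMatrix(
            counts=report.image_level.counts, class_names=IMAGE_CLASS_NAMES
        )
    return PipelineResult(
        report=report, audits=audits, predictions=merged, manifest=manifest
    )


def run_pipeline(
    dataset_dir: Path | str,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path | str] = None,
) -> PipelineResult:
    """Load a dataset directory, cross-validate, and write the outputs.

    Outputs (when ``out_dir`` is given): the echoed config, the manifest,
    merged predictions, per-image audits, and the fold report as JSON and
    as a plain-text table. Runs are reproducible from the echoed config
    and seed alone.
    """
    images = io.load_dataset(dataset_dir)
    result = cross_validate(images, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .config import save_config

        save_config(out / "config.yaml", config)
        io.write_manifest(out / "manifest.csv", result.manifest, config.patching())
        io.write_predictions(out / "predictions.json", result.predictions)
        (out / "audits.json").write_text(
            json.dumps([a.to_dict() for a in result.audits], indent=2, sort_keys=True)
        )
        (out / "report.json").write_text(
            json.dumps(result.report.to_dict(), indent=2, sort_keys=True)
        )
        (out / "report.txt").write_text(result.report.render())
    return result


def save_classifier(path: Path | str, classifier) -> None:
    """Persist a trained backend; the file is an opaque blob."""
    with open(path, "wb") as fh:
        pickle.dump(classifier, fh)


def load_classifier(path: Path | str):
    with open(path, "rb") as fh:
        return pickle.load(fh)
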