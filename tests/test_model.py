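"""Stratified folds, patch resizing, classifier backends, prediction maps."""

from collections import Counter

import numpy as np
import pytest

from nbihisto import model, patching
from nbihisto.model import TrainConfig
from nbihisto.types import InputError


class TestStratifiedFolds:
    def test_nine_units_three_labels(self):
        units = [(f"u{i}", i % 3 + 1) for i in range(9)]
        folds = model.stratified_folds(units, k=3, seed=0)
        for fold in range(3):
            members = folds.units_in(fold)
            labels = [dict(units)[m] for m in members]
            assert sorted(labels) == [1, 2, 3]

    def test_reference_cohort_splits_evenly(self):
        """210 lesions with label counts (53, 120, 20, 17) split 70/70/70."""
        units = []
        for label, count in zip((1, 2, 3, 4), (53, 120, 20, 17)):
            units += [(f"L{label}_{i}", label) for i in range(count)]
        folds = model.stratified_folds(units, k=3, seed=0)
        sizes = Counter(folds.mapping.values())
        assert sorted(sizes.values()) == [70, 70, 70]
        # per-label fold counts differ by at most one
        for label, count in zip((1, 2, 3, 4), (53, 120, 20, 17)):
            per_fold = Counter(
                folds.mapping[u] for u, l in units if l == label
            ).values()
            assert max(per_fold) - min(per_fold) <= 1

    def test_deterministic_and_order_invariant(self):
        units = [(f"u{i}", i % 4 + 1) for i in range(40)]
        a = model.stratified_folds(units, seed=3)
        b = model.stratified_folds(list(reversed(units)), seed=3)
        c = model.stratified_folds(units, seed=4)
        assert a.mapping == b.mapping
        assert a.mapping != c.mapping

    def test_every_unit_appears_exactly_once(self):
        units = [(f"u{i}", 1 + i % 2) for i in range(17)]
        folds = model.stratified_folds(units, k=3, seed=0)
        assert sorted(folds.mapping) == sorted(u for u, _ in units)

    def test_too_many_folds_errors(self):
        with pytest.raises(ValueError):
            model.stratified_folds([("a", 1), ("b", 1)], k=3)

    def test_degenerate_stratum_warns(self):
        units = [("a", 1), ("b", 1), ("c", 1), ("d", 2)]
        with pytest.warns(UserWarning, match="degenerate"):
            model.stratified_folds(units, k=3, seed=0)


class TestResizePatch:
    def test_constant_patch_stays_constant(self):
        patch = np.full((128, 128, 3), 77, dtype=np.uint8)
        out = model.resize_patch(patch)
        assert out.shape == (224, 224, 3)
        assert (out == 77).all()

    def test_corners_agree_with_nearest_neighbor(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        out = model.resize_patch(patch)
        for (ro, co), (ri, ci) in [((0, 0), (0, 0)), ((0, -1), (0, -1)),
                                   ((-1, 0), (-1, 0)), ((-1, -1), (-1, -1))]:
            assert (out[ro, co] == patch[ri, ci]).all()

    def test_output_range_and_dtype(self):
        rng = np.random.default_rng(1)
        patch = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        out = model.resize_patch(patch)
        assert out.dtype == np.uint8

    def test_wrong_channels_raise(self):
        with pytest.raises(ValueError):
            model.resize_patch(np.zeros((128, 128)))


class TestTrainConfig:
    def test_reference_hyperparameters(self):
        cfg = model.REFERENCE_TRAIN_CONFIG
        assert (cfg.optimizer, cfg.loss) == ("adam", "cross_entropy")
        assert (cfg.epochs, cfg.batch_size) == (50, 256)
        assert cfg.learning_rate == pytest.approx(5e-5)
        assert (cfg.n_classes, cfg.input_size) == (7, 224)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(n_classes=5)


@pytest.fixture(scope="module")
def small_manifest(request):
    cohort = request.getfixturevalue("clean_cohort")
    manifest = patching.build_manifest(cohort.images)
    images = {im.image_id: im for im in cohort.images}
    return manifest, images


class TestBackendsAndPrediction:
    def test_oracle_backend_reproduces_manifest(self, small_manifest):
        manifest, images = small_manifest
        oracle = model.OracleBackend(manifest)
        preds = model.predict_patches(oracle, manifest.records, images)
        flat = {
            (iid, r, c): cat
            for iid, entries in preds.items() for r, c, cat in entries
        }
        for rec in manifest.records:
            assert flat[(rec.image_id, *rec.origin)] == rec.category

    def test_constant_backend_is_right_only_for_its_class(self, small_manifest):
        manifest, images = small_manifest
        preds = model.predict_patches(
            model.ConstantBackend(0), manifest.records[:50], images
        )
        cats = [c for entries in preds.values() for _, _, c in entries]
        assert set(cats) == {0}

    def test_empty_record_list(self, small_manifest):
        _, images = small_manifest
        assert model.predict_patches(model.ConstantBackend(1), [], images) == {}

    def test_missing_image_errors(self, small_manifest):
        manifest, _ = small_manifest
        with pytest.raises(InputError):
            model.predict_patches(model.ConstantBackend(1), manifest.records, {})

    def test_prediction_order_equivariance(self, small_manifest):
        """Permuting the records permutes the per-image prediction lists
        identically; the categories themselves do not change."""
        manifest, images = small_manifest
        records = manifest.records[:40]
        oracle = model.OracleBackend(manifest)
        fwd = model.predict_patches(oracle, records, images)
        rev = model.predict_patches(
            model.OracleBackend(manifest), list(reversed(records)), images
        )
        for iid in fwd:
            assert sorted(fwd[iid]) == sorted(rev[iid])
            assert fwd[iid] == list(reversed(rev[iid]))

    def test_untrained_backend_refuses_to_predict(self):
        with pytest.raises(InputError):
            model.SpectralChromaBackend().predict([np.zeros((224, 224, 3))])

    def test_train_classifier_learns_separable_phantoms(self, small_manifest):
        """A light trainable backend reaches high held-out patch accuracy on
        strongly separable textures."""
        manifest, images = small_manifest
        units = sorted(
            {(p["lesion_id"], p["label"]) for p in manifest.provenance.values()}
        )
        folds = model.stratified_folds(units, k=3, seed=0)
        clf = model.train_classifier(manifest, folds, val_fold=0, images=images)
        image_fold = {
            iid: folds.mapping[p["lesion_id"]]
            for iid, p in manifest.provenance.items()
        }
        val = [r for r in manifest.records if image_fold[r.image_id] == 0]
        preds = model.predict_patches(clf, val, images)
        flat = {
            (iid, r, c): cat
            for iid, entries in preds.items() for r, c, cat in entries
        }
        correct = sum(
            1 for r in val if flat[(r.image_id, *r.origin)] == r.category
        )
        assert correct / len(val) > 0.9

    def test_empty_training_split_errors(self, small_manifest):
        manifest, images = small_manifest
        units = sorted(
            {(p["lesion_id"], p["label"]) for p in manifest.provenance.values()}
        )
        # all units in the validation fold leaves nothing to train on
        from nbihisto.types import FoldAssignment

        all_in_zero = FoldAssignment(
            unit="lesion", k=3, mapping={u: 0 for u, _ in units}, seed=0
        )
        with pytest.raises(InputError):
            model.train_classifier(manifest, all_in_zero, 0, images)
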