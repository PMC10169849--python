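"""Grid generation, admission rules, category assignment, manifest building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbihisto import patching, quality
from nbihisto.patching import PatchingConfig
from nbihisto.types import AnnotatedImage, QualityMasks, UndefinedFractionError

class TestGridOrigins:
    @pytest.mark.parametrize(
        "w, h, expected_count",
        [(256, 256, 25), (128, 128, 1), (127, 512, 0), (512, 127, 0),
         (384, 384, 81), (160, 128, 2)],
    )
    def test_counts_match_stride_formula(self, w, h, expected_count):
        assert len(patching.grid_origins(w, h)) == expected_count

    def test_raster_scan_order_and_alignment(self):
        origins = patching.grid_origins(192, 192)
        assert origins[0] == (0, 0)
        assert origins[1] == (0, 32)  # rightwards first, then downwards
        assert origins[3] == (32, 0)
        assert all(r % 32 == 0 and c % 32 == 0 for r, c in origins)
        assert all(r <= 192 - 128 and c <= 192 - 128 for r, c in origins)

    @settings(deadline=None, max_examples=50)
    @given(
        w=st.integers(1, 600), h=st.integers(1, 600),
        patch=st.integers(1, 130), stride=st.integers(1, 64),
    )
    def test_count_formula_holds_generally(self, w, h, patch, stride):
        origins = patching.grid_origins(w, h, patch, stride)
        per_axis = lambda dim: (dim - patch) // stride + 1 if dim >= patch else 0
        assert len(origins) == per_axis(w) * per_axis(h)
        assert len(set(origins)) == len(origins)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            patching.grid_origins(256, 256, patch=0)


def _masks_from(black=None, hal=None, shape=(128, 128)):
    b = np.zeros(shape, bool) if black is None else black
    h = np.zeros(shape, bool) if hal is None else hal
    return QualityMasks(blackout=b, halation=h, effective=~b & ~h)


class TestPatchFractions:
    def test_fully_blacked_window(self):
        masks = _masks_from(black=np.ones((128, 128), bool))
        assert patching.patch_fractions((0, 0), masks) == (1.0, 0.0)

    def test_pixel_count_oracle(self):
        """1,638 of 16,384 flagged pixels is just below the 10% bound."""
        black = np.zeros((128, 128), bool)
        black.flat[:1638] = True
        frac, _ = patching.patch_fractions((0, 0), _masks_from(black=black))
        assert frac == pytest.approx(1638 / 16384)
        assert frac < 0.10

    def test_clean_window(self):
        assert patching.patch_fractions((0, 0), _masks_from()) == (0.0, 0.0)

    def test_roi_denominator(self):
        """Fractions are taken over the window's ROI overlap, not 128^2."""
        black = np.zeros((128, 128), bool)
        black[:, :32] = True
        roi = np.zeros((128, 128), bool)
        roi[:, :64] = True
        frac, _ = patching.patch_fractions((0, 0), _masks_from(black=black), roi=roi)
        assert frac == pytest.approx(0.5)

    def test_zero_roi_overlap_errors(self):
        roi = np.zeros((128, 128), bool)
        with pytest.raises(UndefinedFractionError):
            patching.patch_fractions((0, 0), _masks_from(), roi=roi)


class TestAdmission:
    @pytest.mark.parametrize(
        "fractions, admitted",
        [((0.11, 0.0), False), ((0.10, 0.05), True), ((0.0, 0.06), False),
         ((0.0, 0.0), True), ((0.100001, 0.0), False), ((0.0, 0.050001), False)],
    )
    def test_strict_exclusion_boundaries(self, fractions, admitted):
        assert patching.admit_patch(fractions) == admitted

    @settings(deadline=None, max_examples=60)
    @given(
        b=st.floats(0, 1), h=st.floats(0, 1),
        bound=st.floats(0.1, 1), delta=st.floats(0, 0.5),
    )
    def test_monotone_in_blackout_bound(self, b, h, bound, delta):
        """Raising the blackout bound never turns an admitted patch away."""
        if patching.admit_patch((b, h), blackout_max=bound):
            assert patching.admit_patch((b, h), blackout_max=bound + delta)


class TestAssignCategory:
    def test_in_focus_lesion_gets_image_label(self):
        lesion = np.ones((128, 128), bool)
        assert patching.assign_category((0, 0), lesion, True, 4) == 4

    def test_out_of_focus_background(self):
        lesion = np.zeros((128, 128), bool)
        assert patching.assign_category((0, 0), lesion, False, 2) == 5

    def test_out_of_focus_lesion(self):
        lesion = np.ones((128, 128), bool)
        assert patching.assign_category((0, 0), lesion, False, 1) == 6

    def test_coverage_below_threshold_is_background(self):
        lesion = np.zeros((128, 128), bool)
        lesion[: int(128 * 0.4)] = True  # 40% coverage
        assert patching.assign_category((0, 0), lesion, True, 3,
                                        coverage_threshold=0.5) == 0

    def test_coverage_at_threshold_is_lesion(self):
        lesion = np.zeros((128, 128), bool)
        lesion[:64] = True
        assert patching.assign_category((0, 0), lesion, True, 3,
                                        coverage_threshold=0.5) == 3

    def test_coverage_over_effective_pixels_only(self):
        """Blackout pixels drop out of the coverage denominator."""
        lesion = np.zeros((128, 128), bool)
        lesion[:64] = True
        effective = np.ones((128, 128), bool)
        effective[64:] = False  # only the lesion half is usable
        assert patching.assign_category(
            (0, 0), lesion, True, 2, effective=effective
        ) == 2

    def test_invalid_label(self):
        with pytest.raises(ValueError):
            patching.assign_category((0, 0), np.ones((128, 128), bool), True, 0)


class TestBuildManifest:
    def _clean_image(self, label=2, n=256):
        rng = np.random.default_rng(5)
        px = np.clip(rng.normal(130, 25, (n, n, 3)), 55, 245).astype(np.uint8)
        return AnnotatedImage(
            image_id="img0", pixels=px,
            lesion_mask=np.zeros((n, n), bool), label=label,
        )

    def test_all_background_sharp_image(self):
        manifest = patching.build_manifest([self._clean_image()])
        assert len(manifest.records) == 25
        assert all(r.category == 0 for r in manifest.records)
        assert manifest.counts[0] == 25

    def test_fully_blacked_out_image_yields_nothing(self):
        img = self._clean_image()
        dark = AnnotatedImage(
            image_id="dark",
            pixels=np.full_like(img.pixels, 10),
            lesion_mask=img.lesion_mask, label=2,
        )
        manifest = patching.build_manifest([dark])
        assert manifest.records == []

    def test_counts_match_brute_force_recount(self, artifact_cohort):
        """Manifest bookkeeping equals a naive per-window recount."""
        cfg = PatchingConfig()
        for image in artifact_cohort.images[:2]:
            manifest = patching.build_manifest([image], cfg)
            masks = quality.effective_mask(image.pixels, image.roi)
            expected = []
            for r0 in range(0, image.shape[0] - cfg.patch_size + 1, cfg.stride):
                for c0 in range(0, image.shape[1] - cfg.patch_size + 1, cfg.stride):
                    sl = np.s_[r0 : r0 + cfg.patch_size, c0 : c0 + cfg.patch_size]
                    bf = masks.blackout[sl].mean()
                    hf = masks.halation[sl].mean()
                    if bf > cfg.blackout_max or hf > cfg.halation_max:
                        continue
                    eff = masks.effective[sl]
                    if not eff.any():
                        continue
                    score = quality.focus_score(
                        image.pixels[sl][..., 1], cfg.focus_cutoff
                    )
                    cov = (image.lesion_mask[sl] & eff).sum() / eff.sum()
                    if score.value >= cfg.focus_threshold:
                        cat = image.label if cov >= 0.5 else 0
                    else:
                        cat = 6 if cov >= 0.5 else 5
                    expected.append(((r0, c0), cat))
            got = [(r.origin, r.category) for r in manifest.records]
            assert got == expected

    def test_records_inside_image_and_admissible(self, artifact_cohort):
        manifest = patching.build_manifest(artifact_cohort.images[:3])
        for r in manifest.records:
            assert 0 <= r.origin[0] <= 384 - 128
            assert 0 <= r.origin[1] <= 384 - 128
            assert r.blackout_fraction <= 0.10
            assert r.halation_fraction <= 0.05

    def test_counts_sum_to_records(self, artifact_cohort):
        manifest = patching.build_manifest(artifact_cohort.images[:3])
        assert sum(manifest.counts.values()) == len(manifest.records)
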