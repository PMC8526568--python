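"""Correction chain: dark, shading, registration, background, segmentation."""

import numpy as np
import pytest

from lgt.preprocess import (
    AffineTransform,
    apply_affine,
    background_range_mask,
    estimate_affine_from_fiducials,
    segment_cells,
    shading_correct,
    subtract_background,
    subtract_dark,
)
from lgt.stack import CHANNEL_ROLES, BackgroundRegion, CorrectionBundle, RawStack


def _stack(data):
    return RawStack(np.asarray(data, dtype=float))


def _uniform_stack(value, shape=(2, 5, 16, 16)):
    return RawStack(np.full(shape, float(value)))


class TestSubtractDark:
    def test_plain_subtraction_and_clipping(self):
        stack = _uniform_stack(110.0)
        dark = {r: np.full((16, 16), 10.0) for r in CHANNEL_ROLES}
        out = subtract_dark(stack, CorrectionBundle(dark=dark))
        assert np.all(out.data == 100.0)
        low = _uniform_stack(5.0)
        out = subtract_dark(low, CorrectionBundle(dark=dark))
        assert np.all(out.data == 0.0)  # negatives clipped

    def test_zero_dark_is_identity(self):
        stack = _uniform_stack(42.0)
        dark = {r: np.zeros((16, 16)) for r in CHANNEL_ROLES}
        out = subtract_dark(stack, CorrectionBundle(dark=dark))
        np.testing.assert_array_equal(out.data, stack.data)

    def test_missing_dark_frame_is_configuration_error(self):
        stack = _uniform_stack(1.0)
        dark = {r: np.zeros((16, 16)) for r in CHANNEL_ROLES[:-1]}
        with pytest.raises(KeyError, match="ex494"):
            subtract_dark(stack, CorrectionBundle(dark=dark))


class TestShadingCorrect:
    def test_reference_corrects_itself_to_ones(self, rng):
        ref = 1.0 + 0.3 * rng.standard_normal((16, 16))
        ref = np.clip(ref, 0.2, None)
        ref /= ref.mean()
        shading = {r: ref for r in CHANNEL_ROLES}
        data = np.broadcast_to(ref, (1, 5, 16, 16)).copy()
        out = shading_correct(RawStack(data), CorrectionBundle(shading=shading))
        np.testing.assert_allclose(out.data, 1.0)

    def test_uniform_reference_is_identity(self):
        shading = {r: np.ones((16, 16)) for r in CHANNEL_ROLES}
        stack = _uniform_stack(7.0)
        out = shading_correct(stack, CorrectionBundle(shading=shading))
        np.testing.assert_array_equal(out.data, stack.data)

    def test_nonpositive_reference_rejected(self):
        bad = np.ones((16, 16))
        bad[0, 0] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            CorrectionBundle(shading={"donor": bad})

    def test_known_shading_field_round_trip(self, clean_scene):
        """Dark+shading corrections recover the unshaded truth exactly."""
        (stack, bundle, truth), cfg = clean_scene
        corrected = shading_correct(subtract_dark(stack, bundle), bundle)
        ref_cfg = cfg.artifact_free()
        from lgt.synthetic import generate_latent_fields, render_channels
        ref_truth = generate_latent_fields(ref_cfg)  # same latent stream, no shading
        ref_stack, _ = render_channels(ref_truth, ref_cfg)
        # clean_scene keeps bleed-through; compare the unmixed channels
        for role in ("donor", "acceptor", "ex409", "ex494"):
            np.testing.assert_allclose(
                corrected.channel(role), ref_stack.channel(role), atol=1e-8
            )


class TestAffine:
    def test_exact_recovery_from_three_points(self):
        true = AffineTransform(np.array([[1.01, 0.02, 1.5], [-0.01, 0.99, -0.8]]))
        src = np.array([[10.0, 10.0], [40.0, 12.0], [20.0, 45.0]])
        est = estimate_affine_from_fiducials(src, true.apply_points(src))
        np.testing.assert_allclose(est.matrix, true.matrix, atol=1e-9)
        assert est.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_jittered_points_recover_within_tolerance(self, rng):
        true = AffineTransform(np.array([[1.0, 0.003, 1.2], [-0.003, 1.0, -0.7]]))
        src = rng.uniform(5, 90, size=(10, 2))
        dst = true.apply_points(src) + rng.normal(0, 0.1, size=(10, 2))
        est = estimate_affine_from_fiducials(src, dst)
        assert np.abs(est.matrix - true.matrix).max() < 1e-2 * 10  # offsets in px

    def test_identity_correspondence_gives_identity(self):
        pts = np.array([[1.0, 2.0], [30.0, 4.0], [15.0, 50.0], [60.0, 60.0]])
        est = estimate_affine_from_fiducials(pts, pts)
        np.testing.assert_allclose(est.matrix, AffineTransform.identity().matrix,
                                   atol=1e-10)

    def test_collinear_or_few_points_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_affine_from_fiducials(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            estimate_affine_from_fiducials(line[:2], line[:2])

    def test_apply_identity_unchanged(self, small_scene):
        stack, _, _ = small_scene
        out, valid = apply_affine(stack, AffineTransform.identity(),
                                  ("ex409", "ex494"))
        np.testing.assert_array_equal(out.data, stack.data)
        assert valid.all()

    def test_integer_translation_is_exact_shift(self):
        data = np.zeros((1, 5, 20, 20))
        data[0, :, 10, 7] = 1.0
        stack = RawStack(data)
        # transform maps moving (7 shifted) coords to reference: dst = src + (2, 3)
        t = AffineTransform.from_translation(2.0, 3.0)
        out, valid = apply_affine(stack, t, ("donor",))
        assert out.data[0, 0, 12, 10] == pytest.approx(1.0)
        assert out.data[0, 0].sum() == pytest.approx(1.0)

    def test_round_trip_on_smooth_image(self, rng):
        from scipy import ndimage
        img = ndimage.gaussian_filter(rng.standard_normal((40, 40)), 4)
        data = np.broadcast_to(img, (1, 5, 40, 40)).copy()
        t = AffineTransform(np.array([[1.0, 0.01, 0.6], [-0.01, 1.0, -0.4]]))
        fwd, _ = apply_affine(RawStack(data), t, ("donor",))
        back, valid = apply_affine(fwd, t.inverse(), ("donor",))
        inner = np.zeros((40, 40), dtype=bool)
        inner[3:-3, 3:-3] = True
        err = np.abs(back.data[0, 0] - data[0, 0])[inner & valid]
        assert err.max() < 5e-3  # bilinear interpolation tolerance


class TestBackground:
    def test_region_mean_subtracted_per_frame(self):
        data = np.full((2, 5, 30, 30), 50.0)
        data[:, :, :10, :10] = 7.2  # cell-free corner
        stack = RawStack(data)
        out, levels, sds = subtract_background(stack, BackgroundRegion(0, 10, 0, 10))
        np.testing.assert_allclose(levels, 7.2, rtol=1e-12)
        assert out.data[0, 0, 20, 20] == pytest.approx(50.0 - 7.2)
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)

    def test_zero_background_is_identity(self):
        data = np.full((1, 5, 30, 30), 5.0)
        data[:, :, :10, :10] = 0.0
        out, _, _ = subtract_background(RawStack(data), BackgroundRegion(0, 10, 0, 10))
        assert out.data[0, 0, 20, 20] == pytest.approx(5.0)

    def test_drifting_background_removed(self, rng):
        """Per-frame subtraction tracks a background ramp to within read noise."""
        read_sd = 2.0
        t_ramp = np.linspace(0, 30, 6)
        data = t_ramp[:, None, None, None] + rng.normal(
            0, read_sd, size=(6, 5, 40, 40)
        )
        out, levels, _ = subtract_background(RawStack(data), BackgroundRegion(0, 20, 0, 20))
        resid = out.data[:, :, 20:, 20:].mean(axis=(2, 3)) - 0.0
        assert np.abs(resid).max() < read_sd

    def test_small_region_rejected(self):
        with pytest.raises(ValueError, match="25 pixels"):
            subtract_background(_uniform_stack(1.0), BackgroundRegion(0, 4, 0, 4))

    def test_overlap_with_mask_warns_but_proceeds(self):
        stack = _uniform_stack(1.0, (1, 5, 30, 30))
        masks = np.ones((1, 30, 30), dtype=bool)
        with pytest.warns(UserWarning, match="overlaps"):
            subtract_background(stack, BackgroundRegion(0, 10, 0, 10), masks)


class TestSegmentation:
    def test_two_level_frame_segmented_exactly(self):
        frame = np.full((40, 40), 10.0)
        truth = np.zeros((40, 40), dtype=bool)
        truth[10:30, 12:32] = True
        frame[truth] = 100.0
        data = np.zeros((1, 5, 40, 40))
        data[0, 0] = frame
        masks = segment_cells(RawStack(data), "donor")
        np.testing.assert_array_equal(masks.masks[0], truth)

    def test_constant_frame_yields_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            masks = segment_cells(_uniform_stack(3.0, (1, 5, 20, 20)), "donor")
        assert not masks.masks.any()

    @pytest.mark.parametrize("seed", range(20))
    def test_snr5_iou_benchmark(self, seed):
        """At SNR 5 the recovered mask overlaps truth with IoU >= 0.9."""
        rng = np.random.default_rng(seed)
        truth = np.zeros((60, 60), dtype=bool)
        rr, cc = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        truth[((rr - 30) / 20) ** 2 + ((cc - 28) / 15) ** 2 <= 1] = True
        signal, noise_sd = 50.0, 10.0  # SNR 5
        data = np.zeros((1, 5, 60, 60))
        data[0, 0] = truth * signal + rng.normal(0, noise_sd, (60, 60))
        masks = segment_cells(RawStack(data), "donor")
        inter = (masks.masks[0] & truth).sum()
        union = (masks.masks[0] | truth).sum()
        assert inter / union >= 0.9

    def test_largest_component_retained(self):
        data = np.zeros((1, 5, 40, 40))
        data[0, 0, 5:30, 5:30] = 100.0  # main cell
        data[0, 0, 35:38, 35:38] = 100.0  # debris
        masks = segment_cells(RawStack(data), "donor")
        assert not masks.masks[0, 36, 36]
        assert masks.masks[0, 10, 10]


class TestBackgroundRangeMask:
    def test_any_channel_failure_invalidates(self):
        data = np.full((1, 5, 10, 10), 100.0)
        data[0, 4, 3, 3] = 1.0  # below range in one channel only
        levels = np.zeros((1, 5))
        sds = np.full((1, 5), 2.0)
        valid = background_range_mask(RawStack(data), levels, sds, k=2.0)
        assert not valid[0, 3, 3]
        assert valid[0, 0, 0]

    def test_noiseless_k0_matches_signal_support(self):
        data = np.zeros((1, 5, 20, 20))
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        data[0, :, cell] = 50.0
        valid = background_range_mask(
            RawStack(data), np.zeros((1, 5)), np.zeros((1, 5)), k=0.0
        )
        np.testing.assert_array_equal(valid[0], cell)

    def test_k2_excludes_background_pixels(self, small_scene):
        """On a rendered scene, k=2 removes >=99% of true background pixels."""
        from lgt.preprocess import subtract_background, subtract_dark, shading_correct

        stack, bundle, truth = small_scene
        corrected = shading_correct(subtract_dark(stack, bundle), bundle)
        corrected, levels, sds = subtract_background(corrected, bundle.background)
        valid = background_range_mask(corrected, np.zeros_like(levels), sds, k=2.0)
        bg = ~truth.mask
        frac_excluded = 1.0 - valid[:, bg].mean()
        assert frac_excluded >= 0.99
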