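"""Per-line corrections: scars, medians, refinement, masked variants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import afmflatten as af
from afmflatten import line_ops
from afmflatten.image import DegenerateMaskError, HeightImage


def _img(a):
    return HeightImage(np.asarray(a, float))


class TestDetectScars:
    def test_constant_image_has_no_scars(self):
        assert not line_ops.detect_scars(_img(np.zeros((8, 8)))).any()

    def test_planted_span_is_flagged(self, rng):
        noise = rng.normal(0, 0.05, (64, 128))
        img = noise.copy()
        # amplitude far above the detection threshold of the centred
        # line-difference statistics
        img[30, 40:60] += 10 * 0.05 * np.sqrt(2) * 2
        mask = line_ops.detect_scars(_img(img))
        flagged = np.argwhere(mask)
        assert mask[30, 42:58].all()          # interior of the span
        # the planted span dominates the flags on its line; isolated noise
        # flags elsewhere are tolerated (they sit at the rule's threshold)
        assert mask[30].sum() >= 18
        assert mask.sum() <= mask[30].sum() + 0.02 * mask.size
        # rule-evaluation oracle: every flagged pixel really does deviate
        # from both neighbours beyond twice the robust diff sigma
        d = np.diff(img, axis=0)
        d = d - np.median(d, axis=1, keepdims=True)
        sigma = 1.4826 * np.median(np.abs(d))
        for r, c in flagged:
            if 0 < r < 63:
                up = img[r, c] - img[r - 1, c] - np.median(img[r] - img[r - 1])
                down = img[r, c] - img[r + 1, c] - np.median(img[r] - img[r + 1])
                assert min(abs(up), abs(down)) > 2 * sigma

    def test_smooth_gradient_not_flagged(self):
        ramp = np.linspace(0, 5, 64)[:, None] * np.ones((1, 64))
        assert not line_ops.detect_scars(_img(ramp)).any()

    def test_needs_three_lines(self):
        with pytest.raises(ValueError):
            line_ops.detect_scars(_img(np.zeros((2, 8))))


class TestRepairScars:
    def test_empty_mask_is_identity(self, rng):
        img = _img(rng.normal(size=(16, 16)))
        out = line_ops.repair_scars(img, np.zeros((16, 16), bool))
        assert np.array_equal(out.heights, img.heights)

    def test_single_pixel_over_constant_background(self):
        field = np.full((8, 8), 2.0)
        field[4, 4] = 50.0
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        out = line_ops.repair_scars(_img(field), mask)
        assert out.heights[4, 4] == 2.0
        assert (out.heights != field).sum() == 1

    def test_replacement_is_five_point_median_of_ramp(self):
        # direct median oracle on a linear ramp line
        field = np.tile(np.arange(16.0), (6, 1))
        field[3, 5:8] += 30
        mask = np.zeros((6, 16), bool)
        mask[3, 5:8] = True
        out = line_ops.repair_scars(_img(field), mask)
        for c in (5, 6, 7):
            expected = np.median(field[2, c - 2 : c + 3])
            assert out.heights[3, c] == expected

    def test_scar_on_first_line_uses_following_line(self):
        field = np.full((5, 8), 1.0)
        field[0, 2:5] = 40
        mask = np.zeros((5, 8), bool)
        mask[0, 2:5] = True
        out = line_ops.repair_scars(_img(field), mask)
        assert np.all(out.heights[0, 2:5] == 1.0)


class TestMedianOffsetCorrection:
    def test_odd_length_example(self):
        out, offs = line_ops.median_offset_correction(_img([[1, 2, 3]]))
        assert np.array_equal(out.heights, [[-1, 0, 1]])
        assert offs.values[0] == 2

    def test_idempotent_on_zero_median_lines(self):
        img = _img([[-1, 0, 1], [-2, 0, 2]])
        out, offs = line_ops.median_offset_correction(img)
        assert np.array_equal(out.heights, img.heights)
        assert not offs.values.any()

    def test_all_output_medians_are_zero(self, rng):
        img = _img(rng.normal(size=(32, 33)))
        out, offs = line_ops.median_offset_correction(img)
        assert np.allclose(np.median(out.heights, axis=1), 0, atol=1e-12)
        # offsets are invertible bookkeeping (up to float associativity)
        assert np.allclose(
            out.heights + offs.values[:, None], img.heights, atol=1e-12, rtol=0
        )


class TestMedianDifferenceCorrection:
    def test_identical_lines_unchanged(self):
        img = _img(np.tile(np.arange(8.0), (4, 1)))
        out, offs = line_ops.median_difference_correction(img)
        assert np.array_equal(out.heights, img.heights)
        assert not offs.values.any()

    def test_constant_shift_removed_exactly(self):
        base = np.arange(16.0)
        img = _img([base, base + 5.0])
        out, offs = line_ops.median_difference_correction(img)
        assert np.allclose(out.heights[1], base)
        assert offs.values[1] == 5.0

    def test_step_columns_excluded_from_median(self):
        # exclusion-then-median oracle: a 30%-of-columns step larger than
        # 2x the std of the differences must not bias the offset
        base = np.zeros(100)
        line2 = base + 2.0
        line2[:30] += 8.0  # topographic step
        img = _img([base, line2])
        out, offs = line_ops.median_difference_correction(img)
        d = line2 - base
        keep = np.abs(d - np.median(d)) <= 2 * d.std()
        assert offs.values[1] == np.median(d[keep]) == 2.0
        assert np.allclose(out.heights[1][30:], 0.0)

    def test_scar_lines_skipped(self):
        base = np.zeros(64)
        img = _img([base, base + 3.0, base])
        scars = np.zeros((3, 64), bool)
        scars[1, :] = True  # whole line flagged
        out, offs = line_ops.median_difference_correction(img, scars=scars)
        assert offs.values[1] == 0.0
        assert np.array_equal(out.heights[1], base + 3.0)


class TestRunningAverageRefinement:
    def test_flat_noise_free_field_unchanged(self):
        img = _img(np.ones((32, 16)))
        out, offs = line_ops.running_average_refinement(img)
        assert np.allclose(out.heights, img.heights, atol=1e-12)

    def test_planted_offsets_recovered_on_flat_topography(self):
        # full 1-D stack on a noise-free flat field recovers the planted
        # per-line offsets to numerical precision
        rng = np.random.default_rng(1)
        planted = rng.uniform(-5, 5, 64)
        img = _img(np.zeros((64, 64)) + planted[:, None])
        s1, o1 = line_ops.median_offset_correction(img)
        s2, o2 = line_ops.median_difference_correction(s1)
        s3, o3 = line_ops.running_average_refinement(s2)
        total = o1.values + o2.values + o3.values
        assert np.allclose(total, planted, atol=1e-9)
        assert np.allclose(s3.heights, 0, atol=1e-9)

    def test_noisy_offsets_recovered_within_sampling_error(self):
        rng = np.random.default_rng(2)
        planted = rng.uniform(-5, 5, 128)
        img = _img(rng.normal(0, 0.5, (128, 256)) + planted[:, None])
        s1, o1 = line_ops.median_offset_correction(img)
        s2, o2 = line_ops.median_difference_correction(s1)
        s3, o3 = line_ops.running_average_refinement(s2)
        err = o1.values + o2.values + o3.values - planted
        err -= err.mean()
        # sampling error of a per-line median of 256 noisy pixels
        assert err.std() < 3 * 0.5 * 1.2533 / np.sqrt(256)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            line_ops.running_average_refinement(_img(np.zeros((8, 8))), k=0)


class TestMaskedMedianCorrection:
    def test_full_mask_equals_median_offset_correction(self, rng):
        img = _img(rng.normal(size=(16, 17)))
        a, oa = line_ops.masked_median_correction(img, np.ones((16, 17), bool))
        b, ob = line_ops.median_offset_correction(img)
        assert np.array_equal(a.heights, b.heights)
        assert np.array_equal(oa.values, ob.values)

    def test_feature_outside_mask_preserved(self):
        # masked-median oracle: background at 2 nm, tall feature excluded
        field = np.full((4, 10), 2.0)
        field[2, 6:9] = 30.0
        mask = field < 10
        img = _img(field)
        out, offs = line_ops.masked_median_correction(img, mask)
        assert np.all(offs.values == 2.0)
        assert np.allclose(out.heights[2, 6:9], 28.0)  # height above background kept

    def test_maskless_line_takes_fallback(self):
        field = np.zeros((3, 8))
        mask = np.ones((3, 8), bool)
        mask[1] = False  # line fully covered by a feature
        fallback = af.LineOffsets(np.array([0.0, 7.5, 0.0]))
        out, offs = line_ops.masked_median_correction(_img(field), mask, fallback)
        assert offs.values[1] == 7.5
        assert offs.fallback_lines == (1,)
        assert np.all(out.heights[1] == -7.5)

    def test_fully_empty_mask_is_degenerate(self):
        with pytest.raises(DegenerateMaskError):
            line_ops.masked_median_correction(
                _img(np.zeros((4, 4))), np.zeros((4, 4), bool)
            )


class TestVerticalMedianCorrection:
    def test_transpose_equivalence(self, rng):
        img = _img(rng.normal(size=(24, 32)))
        mask = rng.random((24, 32)) < 0.7
        mask[:, 0] = True  # ensure no empty column
        out, cols = line_ops.vertical_median_correction(img, mask)
        t_out, t_offs = line_ops.masked_median_correction(
            HeightImage(img.heights.T.copy()),
            mask.T,
            fallback=af.LineOffsets(np.median(img.heights, axis=0)),
            min_pixels=int(0.5 * 24),
        )
        assert np.array_equal(out.heights, t_out.heights.T)
        assert np.array_equal(cols, t_offs.values)

    def test_planted_ripple_removed(self, rng):
        c = np.arange(128.0)
        ripple = 2.0 * np.exp(-c / 40) * np.sin(2 * np.pi * 0.08 * c)
        img = _img(rng.normal(0, 0.1, (64, 128)) + ripple[None, :])
        out, cols = line_ops.vertical_median_correction(img, np.ones((64, 128), bool))
        residual = np.median(out.heights, axis=0)
        assert np.allclose(residual, 0, atol=1e-9)
        assert np.abs(out.heights.mean(axis=0)).max() < 0.1

    def test_near_identity_on_ripple_free_field(self, rng):
        img = _img(rng.normal(0, 0.5, (64, 64)))
        out, cols = line_ops.vertical_median_correction(img, np.ones((64, 64), bool))
        # only the per-column noise median is removed
        assert np.abs(cols).max() < 4 * 0.5 * 1.2533 / np.sqrt(64)


class TestPerLineConstancyInvariant:
    """Every 1-D operation subtracts only a constant per line."""

    @given(seed=st.integers(0, 1000))
    def test_line_ops_subtract_constants_only(self, seed):
        rng = np.random.default_rng(seed)
        img = _img(rng.normal(0, 1, (24, 16)) + rng.uniform(-3, 3, 24)[:, None])
        mask = rng.random((24, 16)) < 0.8
        mask[:, 0] = True
        results = []
        results.append(line_ops.median_offset_correction(img))
        results.append(line_ops.median_difference_correction(img))
        results.append(line_ops.running_average_refinement(img, k=5, iterations=2))
        results.append(line_ops.masked_median_correction(img, mask))
        for out, offs in results:
            diff = out.heights - img.heights
            assert np.all(diff.max(axis=1) - diff.min(axis=1) < 1e-12)
            # and adding the offsets back reproduces the input
            assert np.allclose(
                out.heights + offs.values[:, None], img.heights, atol=1e-12
            )


def test_noise_estimate_tracks_true_sigma(rng):
    img = _img(rng.normal(0, 0.5, (256, 256)) + rng.uniform(-5, 5, 256)[:, None])
    est = line_ops.estimate_noise_sigma(img)
    assert est == pytest.approx(0.5, rel=0.05)
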