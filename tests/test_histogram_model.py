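"""Histogram building, peak detection, mixture fitting and thresholds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

import afmflatten as af
from afmflatten import histogram_model as hm
from afmflatten.image import DegenerateMaskError


def _hist_from_samples(samples):
    return hm.build_histogram(np.asarray(samples).reshape(1, -1))


class TestBuildHistogram:
    def test_constant_image_collapses_to_one_bin(self):
        h = hm.build_histogram(np.full((16, 16), 3.5))
        assert h.counts.size == 1
        assert h.counts[0] == 256
        assert h.bin_edges[0] < 3.5 < h.bin_edges[1]

    def test_moments_match_sample_statistics(self, rng):
        data = rng.normal(2.0, 1.3, 65536).reshape(256, 256)
        h = hm.build_histogram(data)
        assert h.mean() == pytest.approx(data.mean(), abs=0.02 * 1.3)
        assert h.std() == pytest.approx(data.std(), rel=0.02)

    def test_masked_total_equals_mask_cardinality(self, rng):
        data = rng.normal(size=(64, 64))
        mask = np.zeros((64, 64), bool)
        mask[::2] = True
        h = hm.build_histogram(data, mask)
        assert h.total_pixels == int(mask.sum())
        assert h.counts.sum() == int(mask.sum())

    def test_empty_mask_is_degenerate(self, rng):
        with pytest.raises(DegenerateMaskError):
            hm.build_histogram(rng.normal(size=(32, 32)), np.zeros((32, 32), bool))

    def test_bin_count_bounds(self, rng):
        h = hm.build_histogram(rng.normal(size=(256, 256)))
        assert 128 <= h.counts.size <= 1024


class TestDetectPeaks:
    def test_single_gaussian_gives_one_peak_near_mode(self, rng):
        data = rng.normal(1.0, 0.5, 65536)
        centers = hm.detect_peaks(_hist_from_samples(data))
        assert len(centers) == 1
        assert centers[0] == pytest.approx(1.0, abs=0.1)

    def test_two_separated_levels(self, rng):
        data = np.concatenate(
            [rng.normal(0, 0.05, 30000), rng.normal(5, 0.05, 30000)]
        )
        centers = hm.detect_peaks(_hist_from_samples(data))
        assert len(centers) == 2
        assert centers[0] == pytest.approx(0.0, abs=0.1)
        assert centers[1] == pytest.approx(5.0, abs=0.1)

    def test_capped_at_max_peaks(self, rng):
        data = np.concatenate(
            [rng.normal(5 * i, 0.05, 6000) for i in range(10)]
        )
        centers = hm.detect_peaks(_hist_from_samples(data), max_peaks=8)
        assert len(centers) == 8


class TestFitGaussianMixture:
    def test_single_gaussian_parameter_recovery(self, rng):
        data = rng.normal(0.0, 1.0, 65536)
        hist = _hist_from_samples(data)
        model = hm.fit_gaussian_mixture(hist, hm.detect_peaks(hist))
        assert len(model.peaks) == 1
        assert model.peaks[0].center == pytest.approx(0.0, abs=0.05)
        assert model.peaks[0].sigma == pytest.approx(1.0, rel=0.05)
        assert model.peaks[0].area == pytest.approx(65536, rel=0.05)

    def test_mixing_weights_recovered(self, rng):
        data = np.concatenate(
            [rng.normal(0, 0.1, 70000), rng.normal(5, 0.1, 30000)]
        )
        hist = _hist_from_samples(data)
        model = hm.fit_gaussian_mixture(hist, hm.detect_peaks(hist))
        assert len(model.peaks) == 2
        ratio = model.peaks[0].area / model.peaks[1].area
        assert ratio == pytest.approx(7 / 3, rel=0.10)

    def test_exact_gaussian_has_tiny_residual(self):
        # model-realizable input: counts evaluated from the model itself
        edges = np.linspace(-5, 5, 257)
        x = 0.5 * (edges[:-1] + edges[1:])
        w = edges[1] - edges[0]
        counts = 10000 * w * norm.pdf(x, 0.3, 0.8)
        hist = hm.HeightHistogram(edges, counts, int(counts.sum()))
        model = hm.fit_gaussian_mixture(hist, [0.3])
        assert model.residual < 1e-6
        assert model.peaks[0].sigma == pytest.approx(0.8, rel=1e-4)

    def test_parameter_recovery_from_own_model(self, rng):
        # draw from the fitted model's family and refit
        data = np.concatenate(
            [rng.normal(0, 0.5, 40000), rng.normal(3, 0.7, 20000)]
        )
        hist = _hist_from_samples(data)
        model = hm.fit_gaussian_mixture(hist, hm.detect_peaks(hist))
        assert model.converged
        assert [p.center for p in model.peaks] == pytest.approx([0, 3], abs=0.05)
        assert model.peaks[0].sigma == pytest.approx(0.5, rel=0.05)
        assert model.peaks[1].sigma == pytest.approx(0.7, rel=0.05)


class TestComputeThreshold:
    def _model(self, peaks):
        return hm.HistogramModel(
            [hm.GaussianPeak(*p) for p in peaks], residual=0.0, bin_width=0.05
        )

    def test_single_peak_plain_band(self):
        iv = hm.compute_threshold(self._model([(0, 1, 1)]), j=0, n=2)
        assert (iv.low, iv.high) == (-2, 2)

    def test_symmetric_neighbor_narrows_to_midpoint(self):
        # oracle: solve A1 g1(x) = A2 g2(x) numerically
        model = self._model([(0, 1, 1), (3, 1, 1)])
        iv = hm.compute_threshold(model, j=0, n=4)
        f = lambda x: norm.pdf(x, 0, 1) - norm.pdf(x, 3, 1)
        crossing = brentq(f, 0.1, 2.9)
        assert crossing == pytest.approx(1.5, abs=1e-9)
        assert iv.high == pytest.approx(crossing, abs=1e-9)
        assert iv.low == -4

    def test_unequal_areas_crossing_matches_numeric_root(self):
        model = self._model([(0, 0.8, 5), (2.5, 0.5, 1)])
        iv = hm.compute_threshold(model, j=0, n=4)
        f = lambda x: 5 * norm.pdf(x, 0, 0.8) - 1 * norm.pdf(x, 2.5, 0.5)
        crossing = brentq(f, 0.5, 2.4)
        assert iv.high == pytest.approx(crossing, abs=1e-9)

    def test_auto_selects_highest_peak(self):
        # peak 1 has smaller area but is much sharper -> greater height
        model = self._model([(0, 2.0, 4), (5, 0.2, 1)])
        iv = hm.compute_threshold(model, j="auto", n=2)
        assert iv.peak_index == 1

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(ValueError):
            hm.compute_threshold(self._model([(0, 1, 1)]), j=3, n=2)

    @given(
        centers=st.lists(
            st.floats(-50, 50), min_size=1, max_size=5, unique=True
        ),
        n=st.floats(0.5, 4),
        j=st.integers(0, 4),
    )
    def test_interval_always_contains_selected_center(self, centers, n, j):
        peaks = [hm.GaussianPeak(c, 0.5 + abs(c) % 1, 1 + abs(c)) for c in centers]
        model = hm.HistogramModel(peaks, 0.0, 0.05)
        j = j % len(model.peaks)
        iv = hm.compute_threshold(model, j=j, n=n)
        assert iv.low <= model.peaks[j].center <= iv.high


class TestWeightedSigmaAndImprovement:
    def _model(self, peaks):
        return hm.HistogramModel(
            [hm.GaussianPeak(*p) for p in peaks], residual=0.0, bin_width=0.05
        )

    @pytest.mark.parametrize(
        "peaks,indices,expected",
        [
            ([(0, 2.0, 5)], [0], 2.0),
            ([(0, 1.0, 1), (5, 3.0, 1)], [0, 1], 2.0),
            ([(0, 1.0, 3), (5, 3.0, 1)], [0, 1], 1.5),
        ],
    )
    def test_weighted_sigma(self, peaks, indices, expected):
        assert hm.weighted_sigma(self._model(peaks), indices) == pytest.approx(expected)

    def test_no_change_is_accepted(self):
        m = self._model([(0, 1, 10)])
        v = hm.improvement_check(m, m)
        assert v.accepted

    def test_area_halved_is_rejected_citing_area(self):
        before = self._model([(0, 1, 10)])
        after = self._model([(0, 1, 5)])
        v = hm.improvement_check(before, after)
        assert not v.accepted
        assert "area" in v.reason

    def test_sigma_reduction_with_stable_area_is_accepted(self):
        before = self._model([(0, 1.0, 10)])
        after = self._model([(0, 0.9, 10)])
        v = hm.improvement_check(before, after)
        assert v.accepted
        assert v.sigma_w_after < v.sigma_w_before

    def test_sigma_broadening_is_rejected(self):
        before = self._model([(0, 1.0, 10)])
        after = self._model([(0, 1.5, 10)])
        assert not hm.improvement_check(before, after).accepted

    def test_level_loss_is_rejected_with_band_counts(self, rng):
        # two real levels collapse into one: fixed-band area stays high but
        # the level-count guard must fire
        before_data = np.concatenate([rng.normal(0, 0.1, 5000), rng.normal(5, 0.1, 5000)])
        after_data = rng.normal(0, 0.1, 10000)
        before = hm.fit_model(before_data.reshape(100, 100))
        after = hm.fit_model(after_data.reshape(100, 100))
        v = hm.improvement_check(
            before,
            after,
            levels=2,
            before_heights=before_data,
            after_heights=after_data,
            band_width=0.3,
        )
        assert not v.accepted
        assert "levels" in v.reason
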