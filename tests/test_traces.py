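"""Baseline estimation, peak detection, integration, and hump splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from botanicad import traces
from botanicad.errors import InputError, ParameterError
from botanicad.traces import Trace

from conftest import gaussian_trace


class TestTrace:
    def test_requires_increasing_time(self):
        with pytest.raises(InputError):
            Trace(np.array([0.0, 0.0, 1.0]), np.zeros(3))

    def test_requires_two_samples(self):
        with pytest.raises(InputError):
            Trace(np.array([0.0]), np.array([1.0]))

    def test_irregular_grid_resampled_to_median_spacing(self):
        t = np.array([0.0, 0.1, 0.2, 0.35, 0.4, 0.5])
        tr = Trace(t, np.sin(t)).resampled()
        assert tr.is_uniform()


class TestEstimateBaseline:
    def test_flat_trace_returns_constant(self):
        tr = gaussian_trace([], [], [], baseline=3.7)
        base = traces.estimate_baseline(tr, 1.0)
        assert np.allclose(base.signal, 3.7, atol=1e-9)

    def test_single_gaussian_on_zero_baseline(self):
        tr = gaussian_trace([5.0], [0.05], [1.0])
        base = traces.estimate_baseline(tr, 1.0)
        height = tr.signal.max()
        assert np.max(np.abs(base.signal)) < 0.01 * height

    def test_linear_drift_recovered_within_5_percent(self):
        t = np.arange(0, 10, 0.005)
        slope = 0.8
        drift = slope * t
        y = drift.copy()
        for mu in (2.0, 5.0, 8.0):
            y += 5.0 * np.exp(-0.5 * ((t - mu) / 0.05) ** 2)
        base = traces.estimate_baseline(Trace(t, y), 1.0)
        inner = (t > 1) & (t < 9)  # opening is edge-biased at the run ends
        fit = np.polyfit(t[inner], base.signal[inner], 1)[0]
        assert fit == pytest.approx(slope, rel=0.05)

    def test_window_longer_than_run_raises(self):
        tr = gaussian_trace([5.0], [0.1], [1.0])
        with pytest.raises(ParameterError):
            traces.estimate_baseline(tr, 100.0)


class TestDetectPeaks:
    def test_separated_gaussians_all_found_at_truth_apexes(self):
        centers = [1.0, 2.5, 4.0, 6.0, 8.5]
        tr = gaussian_trace(centers, [0.05] * 5, [1.0, 0.5, 2.0, 0.8, 1.2])
        peaks = traces.detect_peaks(tr, min_height=0.5, min_prominence=0.5)
        assert len(peaks) == len(centers)
        for p, mu in zip(peaks, centers):
            assert abs(p.apex_rt_min - mu) <= tr.dt + 1e-12
            assert p.start_rt_min < p.apex_rt_min < p.end_rt_min

    def test_recall_and_precision_one_on_noiseless_trace(self):
        centers = [1.0, 3.0, 5.0, 7.0]
        tr = gaussian_trace(centers, [0.06] * 4, [1.0] * 4)
        peaks = traces.detect_peaks(tr, 0.1, 0.1)
        assert [round(p.apex_rt_min) for p in peaks] == [1, 3, 5, 7]

    def test_noise_only_trace_yields_no_peaks(self):
        tr = gaussian_trace([], [], [], noise_sd=0.05, seed=3)
        assert traces.detect_peaks(tr, min_height=0.5, min_prominence=0.5) == []

    def test_fused_pair_split_at_bruteforce_valley(self):
        # two equal Gaussians whose overlap leaves a ~50 % valley
        sigma, delta = 0.1, 0.24
        tr = gaussian_trace([5.0 - delta, 5.0 + delta], [sigma] * 2, [1.0, 1.0])
        peaks = traces.detect_peaks(tr, 0.2, 0.2)
        assert len(peaks) == 2
        t, y = tr.time_min, tr.signal
        mid = (t > 5.0 - delta) & (t < 5.0 + delta)
        valley_rt = t[mid][np.argmin(y[mid])]
        assert peaks[0].end_rt_min == pytest.approx(valley_rt, abs=2 * tr.dt)
        assert peaks[1].start_rt_min == pytest.approx(valley_rt, abs=2 * tr.dt)

    def test_areas_of_separated_peaks_recover_truth(self):
        areas = [1.0, 0.5, 2.0]
        tr = gaussian_trace([2.0, 5.0, 8.0], [0.06] * 3, areas)
        peaks = traces.detect_peaks(tr, 0.2, 0.2)
        for p, a in zip(peaks, areas):
            assert p.area == pytest.approx(a, rel=0.01)

    def test_negative_threshold_raises(self):
        tr = gaussian_trace([5.0], [0.1], [1.0])
        with pytest.raises(ParameterError):
            traces.detect_peaks(tr, -1.0, 0.0)


class TestIntegrate:
    def test_unit_gaussian_fully_inside_window(self):
        tr = gaussian_trace([5.0], [0.2], [1.0])
        assert traces.integrate(tr, 3.0, 7.0) == pytest.approx(1.0, abs=1e-3)

    def test_zero_signal_integrates_to_zero(self):
        tr = Trace(np.linspace(0, 10, 500), np.zeros(500))
        assert traces.integrate(tr, 1.0, 9.0) == 0.0

    def test_half_window_of_symmetric_gaussian(self):
        tr = gaussian_trace([5.0], [0.2], [1.0])
        assert traces.integrate(tr, 5.0, 8.0) == pytest.approx(0.5, abs=1e-3)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        a=st.floats(0.5, 4.0), c=st.floats(6.0, 9.5),
        b_frac=st.floats(0.1, 0.9),
    )
    def test_fixed_zero_additivity(self, a, c, b_frac):
        """integrate(a,b) + integrate(b,c) == integrate(a,c)."""
        tr = gaussian_trace([5.0], [0.5], [2.0], baseline=0.3)
        b = a + b_frac * (c - a)
        left = traces.integrate(tr, a, b)
        right = traces.integrate(tr, b, c)
        total = traces.integrate(tr, a, c)
        assert left + right == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_valley_to_valley_subtracts_chord(self):
        tr = gaussian_trace([5.0], [0.2], [1.0], baseline=2.0)
        assert traces.integrate(tr, 3.0, 7.0, "valley-to-valley") == pytest.approx(
            1.0, abs=1e-2
        )

    def test_window_outside_span_raises(self):
        tr = gaussian_trace([5.0], [0.2], [1.0])
        with pytest.raises(InputError):
            traces.integrate(tr, -5.0, 5.0)


def hump_trace(hump_area=50.0, peak_areas=(), peak_centers=(), noise_sd=0.0, seed=0):
    centers = [22.0, 26.0, 30.0, 34.0, 38.0]
    areas = [hump_area / 5.0] * 5
    return gaussian_trace(
        list(centers) + list(peak_centers),
        [2.5] * 5 + [0.06] * len(peak_centers),
        list(areas) + list(peak_areas),
        t0=10.0, t1=50.0, noise_sd=noise_sd, seed=seed,
    )


class TestSplitHump:
    def test_hump_only_has_negligible_narrow_area(self):
        tr = hump_trace(hump_area=50.0)
        narrow, hump = traces.split_hump(tr, (15.0, 45.0), min_height=0.05,
                                         min_prominence=0.05)
        total = traces.integrate(tr, 15.0, 45.0)
        assert sum(p.area for p in narrow) < 0.02 * total
        assert hump == pytest.approx(total, rel=0.02)

    def test_peaks_only_yield_negligible_hump(self):
        tr = gaussian_trace([20.0, 25.0, 30.0], [0.06] * 3, [1.0, 2.0, 1.5],
                            t0=10.0, t1=50.0)
        narrow, hump = traces.split_hump(tr, (15.0, 45.0), min_height=0.5,
                                         min_prominence=0.5)
        total = traces.integrate(tr, 15.0, 45.0)
        assert hump < 0.02 * total
        assert sum(p.area for p in narrow) == pytest.approx(total, rel=0.02)

    def test_mixed_components_recovered_within_5_percent(self):
        peak_areas = [1.0, 0.8, 1.2]
        tr = hump_trace(hump_area=40.0, peak_areas=peak_areas,
                        peak_centers=[24.0, 29.0, 33.0])
        narrow, hump = traces.split_hump(tr, (15.0, 45.0), min_height=0.5,
                                         min_prominence=0.5)
        assert len(narrow) == 3
        for p, a in zip(sorted(narrow, key=lambda p: p.apex_rt_min), peak_areas):
            assert p.area == pytest.approx(a, rel=0.05)
        # most of the hump mass lies inside the 15-45 window
        assert hump == pytest.approx(40.0, rel=0.05)

    def test_conservation_narrow_plus_hump_equals_window_integral(self):
        tr = hump_trace(hump_area=40.0, peak_areas=[1.0, 1.5],
                        peak_centers=[24.0, 31.0], noise_sd=0.02, seed=5)
        narrow, hump = traces.split_hump(tr, (15.0, 45.0), min_height=0.3,
                                         min_prominence=0.3)
        total = traces.integrate(tr, 15.0, 45.0)
        assert sum(p.area for p in narrow) + hump == pytest.approx(
            total, rel=1e-6
        )


class TestMergeDualGain:
    def test_prefers_low_gain_where_high_gain_saturates(self):
        t = np.linspace(0, 10, 2001)
        true = 3.0 * np.exp(-0.5 * ((t - 5) / 0.5) ** 2)
        high = np.minimum(true * 5.0, 10.0)  # saturates at 10
        low = true * 1.0
        merged = traces.merge_dual_gain(Trace(t, high), Trace(t, low), saturation=9.9)
        assert np.allclose(merged.signal, true * 5.0, rtol=1e-6)
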