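"""Error index, peak classification, rates, bursts, phase diagrams."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt import metrics
from cbgt.io_formats import SyntheticTraceSpec, generate_trace


def trace_of(heights, n_windows=None, noise=0.0, baseline=-75.0, seed=0):
    if n_windows is None:
        n_windows = max(len(heights), 1)
    times = tuple(50.0 + 100.0 * k for k in range(len(heights)))
    spec = SyntheticTraceSpec(peak_heights=tuple(heights),
                              peak_times=times, baseline=baseline,
                              noise_sd=noise, n_windows=n_windows)
    return generate_trace(spec, seed=seed), spec


class TestClassifyPeaks:
    def test_all_normal(self):
        tr, spec = trace_of([1.0, 0.95])
        res = metrics.classify_peaks(tr, spec.dt, spec.baseline,
                                     ref_max=1.0, window=spec.window)
        assert (res.n_lost, res.n_incomplete, res.n_normal) == (0, 0, 2)

    def test_mixed_heights(self):
        tr, spec = trace_of([1.0, 0.5, 0.05])
        res = metrics.classify_peaks(tr, spec.dt, spec.baseline,
                                     ref_max=1.0, window=spec.window)
        # 0.05 is below the 10% detection floor: that window is lost
        assert (res.n_lost, res.n_incomplete, res.n_normal) == (1, 1, 1)

    def test_empty_trace_with_expected_windows(self):
        tr, spec = trace_of([], n_windows=3)
        res = metrics.classify_peaks(tr, spec.dt, spec.baseline,
                                     ref_max=1.0, window=spec.window)
        assert (res.n_lost, res.n_incomplete, res.n_normal) == (3, 0, 0)

    def test_counts_are_exhaustive_and_exclusive(self):
        heights = [1.0, 0.97, 0.6, 0.3, 0.02, 0.91, 0.11]
        tr, spec = trace_of(heights)
        res = metrics.classify_peaks(tr, spec.dt, spec.baseline,
                                     ref_max=1.0, window=spec.window)
        assert res.n_lost + res.n_incomplete + res.n_normal == len(heights)

    def test_degenerate_trace_errors(self):
        flat = np.full(1000, -65.0)
        with pytest.raises(ValueError):
            metrics.classify_peaks(flat, 0.1, -65.0)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError):
            metrics.classify_peaks(np.array([0.0]), 0.1, 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           heights=st.lists(
               st.sampled_from([0.05, 0.3, 0.5, 0.8, 0.95, 1.0]),
               min_size=1, max_size=6))
    def test_scale_invariance(self, scale, heights):
        heights = list(heights) + [1.0]  # pin the reference
        tr, spec = trace_of(heights)
        scaled = spec.baseline + (tr - spec.baseline) * scale
        a = metrics.classify_peaks(tr, spec.dt, spec.baseline,
                                   ref_max=1.0, window=spec.window)
        b = metrics.classify_peaks(scaled, spec.dt, spec.baseline,
                                   ref_max=scale, window=spec.window)
        assert (a.n_lost, a.n_incomplete, a.n_normal) == \
            (b.n_lost, b.n_incomplete, b.n_normal)


class TestErrorIndex:
    @pytest.mark.parametrize("inc,norm,expected",
                             [(0, 10, 0.0), (5, 10, 0.5), (3, 4, 0.75)])
    def test_ratio(self, inc, norm, expected):
        res = metrics.EIResult(0, inc, norm, 1.0)
        assert metrics.error_index(res) == pytest.approx(expected)

    def test_undefined_without_normal_peaks(self):
        res = metrics.EIResult(2, 5, 0, 1.0)
        with pytest.raises(metrics.UndefinedEIError):
            metrics.error_index(res)


class TestRatesAndBursts:
    def test_mean_firing_rate(self):
        assert metrics.mean_firing_rate(np.arange(16), 1000.0) == 16.0
        assert metrics.mean_firing_rate([], 1000.0) == 0.0

    def test_rate_shift_invariance(self):
        st_ = np.array([10.0, 400.0, 900.0])
        assert metrics.mean_firing_rate(st_, 1000.0) == \
            metrics.mean_firing_rate(st_ + 50.0, 1000.0)

    def test_rate_invalid_window(self):
        with pytest.raises(ValueError):
            metrics.mean_firing_rate([1.0], 0.0)

    def test_spikes_per_burst(self):
        train = np.array([0.0, 5.0, 10.0, 110.0, 115.0, 120.0])
        assert metrics.spikes_per_burst(train, 50.0) == 3.0
        assert metrics.spikes_per_burst([42.0], 50.0) == 1.0
        tonic = np.arange(0.0, 500.0, 20.0)
        assert metrics.spikes_per_burst(tonic, 1000.0) == len(tonic)
        assert metrics.spikes_per_burst([], 50.0) == 0.0

    def test_spikes_per_burst_invalid_gap(self):
        with pytest.raises(ValueError):
            metrics.spikes_per_burst([1.0], 0.0)


class TestPhaseDiagram:
    def test_functional_relation_has_zero_dispersion(self):
        g = np.linspace(-80.0, -20.0, 5000)
        t = 2.0 * g + 10.0
        pd_ = metrics.phase_diagram(g, t)
        assert pd_.mean_dispersion() < 1.5  # within-bin slope spread only

    def test_independent_noise_has_marginal_spread(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(-80, -20, 20000)
        t = rng.normal(-60.0, 8.0, 20000)
        pd_ = metrics.phase_diagram(g, t)
        assert pd_.mean_dispersion() == pytest.approx(8.0, rel=0.15)

    def test_identical_traces_sit_on_diagonal(self):
        g = np.linspace(-80.0, -20.0, 1000)
        pd_ = metrics.phase_diagram(g, g)
        assert np.allclose(pd_.pairs[:, 0], pd_.pairs[:, 1])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            metrics.phase_diagram(np.zeros(10), np.zeros(11))

    def test_suprathreshold_cutoff(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(-90, -20, 30000)
        # deterministic below -70, scattered above: the cutoff isolates it
        t = np.where(g < -70.0, g, rng.normal(-50.0, 10.0, 30000))
        pd_ = metrics.phase_diagram(g, t)
        above = pd_.mean_dispersion(v_gpi_min=-70.0)
        assert above == pytest.approx(10.0, rel=0.25)
        assert above > pd_.mean_dispersion(v_gpi_min=None)


class TestCalibration:
    def test_reference_from_healthy_rhythm(self):
        heights = [1.0, 0.98, 0.99, 1.0, 0.97]
        tr, spec = trace_of(heights)
        ref_max, window = metrics.calibrate_reference(tr, spec.dt,
                                                      spec.baseline)
        assert ref_max == pytest.approx(1.0, rel=0.02)
        assert window == pytest.approx(100.0, rel=0.05)

    def test_calibration_needs_events(self):
        flat = np.full(5000, -70.0) + 0.01
        with pytest.raises(ValueError):
            metrics.calibrate_reference(flat, 0.1, -70.0)
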