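"""Amplitude estimation, probability weighting, windowed spectra, scaling."""
import numpy as np
import pytest

import recamp
from recamp import (EmbeddingParams, RunConfig, Series, delay_embed,
                    frequency_axis, min_resolvable_frequency,
                    period_distribution, recurrence_amplitude,
                    recurrence_matrix, recurrence_periods,
                    recurrence_spectrum, scale_output, weight_spectrum,
                    windowed_spectrum)
from recamp import synth
from conftest import peak_period


def sine_events(series, eps=10.0, tau=13):
    states = delay_embed(series, EmbeddingParams(2, tau))
    m = recurrence_matrix(states, eps, window_std=series.std)
    return recurrence_periods(m), states


class TestRecurrenceAmplitude:
    def test_sine_diameter_is_twice_amplitude(self, sine20):
        # max-norm diameter of one loop: peak-to-trough along a coordinate
        events, states = sine_events(sine20)
        amps = recurrence_amplitude(events, states)
        weighted_mean = np.average(amps.abar, weights=amps.q_counts)
        assert weighted_mean == pytest.approx(2.0, rel=0.05)

    def test_homogeneous_under_scaling(self, sine20):
        events, states = sine_events(sine20)
        a1 = recurrence_amplitude(events, states)
        scaled = sine20.scaled(3.5)
        events2, states2 = sine_events(scaled)   # eps follows STD: same events
        a2 = recurrence_amplitude(events2, states2, t_grid=a1.T_grid)
        np.testing.assert_allclose(a2.abar, 3.5 * a1.abar, rtol=1e-9)

    def test_euclidean_and_maximum_agree_on_ordering(self, sine20):
        events, states = sine_events(sine20)
        am = recurrence_amplitude(events, states, metric="maximum")
        ae = recurrence_amplitude(events, states, metric="euclidean",
                                  t_grid=am.T_grid)
        present = am.q_counts > 0
        assert np.all(ae.abar[present] >= am.abar[present] - 1e-9)

    def test_empty_events_empty_result(self):
        states = delay_embed(Series(np.arange(10.0), 1.0), EmbeddingParams(2, 1))
        amps = recurrence_amplitude([], states, t_grid=np.arange(2, 5))
        assert np.all(amps.abar == 0) and np.all(amps.q_counts == 0)


class TestWeighting:
    def test_single_period_weighted_equals_abar(self, sine20):
        events, states = sine_events(sine20)
        only = [e for e in events if e.period == events[0].period]
        dist = period_distribution(only, 2, 200)
        amps = recurrence_amplitude(only, states, t_grid=dist.T_grid)
        spec = weight_spectrum(dist, amps, sine20.fs)
        at = spec.T_grid == only[0].period
        assert spec.weighted[at] == pytest.approx(spec.abar[at])
        assert np.all(spec.weighted[~at] == 0)

    def test_grid_mismatch_rejected(self, sine20):
        events, states = sine_events(sine20)
        dist = period_distribution(events, 2, 100)
        amps = recurrence_amplitude(events, states, t_grid=np.arange(2, 50))
        with pytest.raises(ValueError, match="grid"):
            weight_spectrum(dist, amps, sine20.fs)

    def test_weighted_is_elementwise_product(self, sine20):
        spec = recurrence_spectrum(sine20, RunConfig(en=10.0, tau=13, dim=2))
        np.testing.assert_allclose(spec.weighted, spec.prob * spec.abar)
        assert np.all(np.diff(spec.freq) < 0)


class TestWindowedSpectrum:
    def test_stationary_signal_constant_peak_row(self):
        sig = synth.make_wave(synth.WaveSpec("sine", 20.0, 1.0, 4.0))
        tfs = windowed_spectrum(sig, RunConfig(en=10.0, window=500, db=False))
        peaks = {peak_period(row, tfs.T_grid) for row in tfs.values}
        assert len(peaks) == 1
        assert abs(peaks.pop() - 50) <= 1

    def test_window_center_spacing(self, fig4_tfs):
        hop_s = fig4_tfs.window_len * (1 - fig4_tfs.overlap) / fig4_tfs.fs
        np.testing.assert_allclose(np.diff(fig4_tfs.times), hop_s)

    def test_default_window_is_tenth_of_length(self):
        sig = synth.make_wave(synth.WaveSpec("sine", 20.0, 1.0, 3.0))
        tfs = windowed_spectrum(sig, RunConfig(en=10.0, db=False))
        assert tfs.window_len == sig.n // 10

    def test_window_validation(self):
        sig = synth.make_wave(synth.WaveSpec("sine", 20.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="too short"):
            windowed_spectrum(sig, RunConfig(window=1))
        with pytest.raises(ValueError, match="exceeds"):
            windowed_spectrum(sig, RunConfig(window=5000))

    def test_degenerate_window_flagged_zero_row(self):
        flat = Series(np.concatenate([np.zeros(500),
                                      np.sin(2 * np.pi * 20 * np.arange(500) / 1000)]),
                      1000.0)
        tfs = windowed_spectrum(flat, RunConfig(en=10.0, window=500, overlap=0.0,
                                                db=False))
        assert 0 in tfs.degenerate_windows
        assert np.all(tfs.values[0] == 0)

    def test_segment_mean_requires_covered_interval(self, fig4_tfs):
        with pytest.raises(ValueError, match="no window"):
            fig4_tfs.segment_mean(14.9, 15.0)

    def test_step_segments_peak_at_period_multiples(self, fig5_tfs):
        """At small eps missed single-cycle recurrences surface at integer
        multiples of the generating period, never at unrelated bands."""
        for i, f in enumerate([14.0, 33.0, 41.0, 52.0, 67.0]):
            m = fig5_tfs.segment_mean(3 * i, 3 * (i + 1))
            T = peak_period(m, fig5_tfs.T_grid)
            cycles = T / (fig5_tfs.fs / f)
            assert abs(cycles - round(cycles)) <= 0.1
            assert 1 <= round(cycles) <= 3


class TestScaling:
    def test_amp_pow_db_closed_forms(self):
        assert scale_output(np.array([1.0]), "amp", db=True)[0] == 0.0
        assert scale_output(np.array([10.0]), "pow", db=True)[0] == pytest.approx(20.0)
        assert scale_output(np.array([3.0]), "pow")[0] == 9.0

    def test_zero_maps_to_floor(self):
        out = scale_output(np.array([0.0, 1.0]), "amp", db=True)
        assert out[0] == recamp.DB_FLOOR and out[1] == 0.0

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            scale_output(np.array([-1.0]))


class TestFrequencyAxis:
    def test_conversion(self):
        np.testing.assert_allclose(frequency_axis([50, 30], 1000.0),
                                   [20.0, 1000 / 30])

    def test_normalized_mode(self):
        # period-1 orbit of 125 samples -> normalized frequency 1 at T=125
        f = frequency_axis([125, 375], 1.0, ref_period=125)
        np.testing.assert_allclose(f, [1.0, 1 / 3])

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            frequency_axis([0], 1000.0)


def test_min_resolvable_frequency_bound():
    assert min_resolvable_frequency(600, 1000.0) == pytest.approx(5 / 3)
    assert min_resolvable_frequency(1000, 1000.0) == 1.0
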