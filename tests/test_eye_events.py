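import numpy as np
import pytest

from perisacc.eye_events import (EyeTrace, bin_left_edges,
                                 bin_perisaccadic_rates, detect_saccades,
                                 select_snippets)
from perisacc.synthetic import OknParams, generate_eye_trace


def single_saccade_params(amplitude=10.0, peak_speed=300.0):
    return OknParams(saccade_amplitude_mean=amplitude, saccade_amplitude_sd=0.0,
                     saccade_peak_speed=peak_speed, slow_phase_speed=0.0,
                     recenter_gain=0.0, intersaccadic_interval_mean=5000.0,
                     min_intersaccadic_interval=2000.0)


def constant_velocity_trace(speed_deg_s=15.0, duration_s=2.0, fs=500.0):
    t = np.arange(int(duration_s * fs)) * (1000.0 / fs)
    return EyeTrace(time_ms=t, horiz_deg=speed_deg_s * t / 1000.0,
                    vert_deg=np.zeros_like(t), sampling_rate_hz=fs)


class TestDetector:
    def test_single_saccade_detected_at_threshold_crossing(self):
        """One 10 deg, 300 deg/s saccade: onset within one sample (2 ms)."""
        trace, truth = generate_eye_trace(single_saccade_params(), 4.0, seed=2)
        assert len(truth) == 1
        events = detect_saccades(trace)
        assert len(events) == 1
        crossing = truth[0].threshold_crossing_ms(80.0)
        assert abs(events[0].onset_ms - crossing) <= 2.0

    def test_constant_velocity_trace_yields_no_events(self):
        assert detect_saccades(constant_velocity_trace(15.0)) == []

    def test_detector_perfect_on_noise_free_trace(self):
        """Recall and precision are 1 when peak speeds are >= 2x threshold."""
        trace, truth = generate_eye_trace(OknParams(saccade_peak_speed=300.0),
                                          40.0, seed=4)
        events = detect_saccades(trace, speed_threshold_deg_s=80.0)
        det = np.array([e.onset_ms for e in events])
        crossings = np.array([t.threshold_crossing_ms(80.0) for t in truth])
        assert len(det) == len(crossings)
        assert np.all(np.abs(det - crossings) <= 4.0)

    def test_lowering_threshold_never_loses_events(self):
        trace, _ = generate_eye_trace(OknParams(), 30.0, seed=6)
        counts = [len(detect_saccades(trace, thr))
                  for thr in (160.0, 80.0, 40.0)]
        assert counts == sorted(counts)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 2.0, 4.0, 7.0, 9.0])
        with pytest.raises(ValueError):
            EyeTrace(time_ms=t, horiz_deg=np.zeros(5), vert_deg=np.zeros(5),
                     sampling_rate_hz=500.0)

    def test_too_short_trace_rejected(self):
        tr = EyeTrace(time_ms=np.array([0.0, 2.0]), horiz_deg=np.zeros(2),
                      vert_deg=np.zeros(2), sampling_rate_hz=500.0)
        with pytest.raises(ValueError):
            detect_saccades(tr)


def two_saccade_trace(separation_ms=300.0):
    """Two square-ish fast ramps separated by the given onset interval."""
    fs = 500.0
    t = np.arange(int(2.0 * fs)) * 2.0
    x = np.zeros_like(t)
    for onset in (600.0, 600.0 + separation_ms):
        dur = 40.0
        tau = np.clip((t - onset) / dur, 0.0, 1.0)
        x = x + 8.0 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5) * (-1) ** int(onset // 700)
    return EyeTrace(time_ms=t, horiz_deg=x, vert_deg=np.zeros_like(t),
                    sampling_rate_hz=fs)


class TestSnippets:
    def test_isolation_rule_is_asymmetric(self):
        """Two saccades 300 ms apart: the first sees the second inside its
        [-200, 450] ms window and is excluded; the second's companion lies
        300 ms in the past, outside the window, so it stays eligible."""
        trace = two_saccade_trace(300.0)
        events = detect_saccades(trace)
        assert len(events) == 2
        snips = select_snippets(events, trace)
        assert [s.saccade.onset_ms for s in snips] == [events[1].onset_ms]

    def test_isolated_saccade_yields_one_snippet(self):
        trace, _ = generate_eye_trace(single_saccade_params(), 4.0, seed=2)
        events = detect_saccades(trace)
        snips = select_snippets(events, trace,
                                schedule=[(0.0, 4000.0, 30.0)])
        assert len(snips) == 1
        assert snips[0].heading_deg == 30.0

    def test_followup_saccade_at_400ms_excludes_snippet(self):
        trace = two_saccade_trace(400.0)
        events = detect_saccades(trace)
        assert len(events) == 2
        snips = select_snippets(events, trace)
        assert events[0].onset_ms not in [s.saccade.onset_ms for s in snips]

    def test_central_window_convention(self):
        """Gaze at 15 deg: outside a 20 deg-wide central window (half-width
        10 deg) but inside a 40 deg-wide one."""
        fs = 500.0
        t = np.arange(int(4.0 * fs)) * 2.0
        onset, dur = 2000.0, 40.0
        tau = np.clip((t - onset) / dur, 0.0, 1.0)
        x = 15.0 - 8.0 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        trace = EyeTrace(time_ms=t, horiz_deg=x, vert_deg=np.zeros_like(t),
                         sampling_rate_hz=fs)
        events = detect_saccades(trace)
        assert len(events) == 1
        assert select_snippets(events, trace, central_limit_deg=20.0) == []
        assert len(select_snippets(events, trace, central_limit_deg=40.0)) == 1


def make_snippet(onset_ms, heading=0.0):
    from perisacc.eye_events import PerisaccadicSnippet, SaccadeEvent
    return PerisaccadicSnippet(
        saccade=SaccadeEvent(onset_ms=onset_ms, offset_ms=onset_ms + 40.0,
                             amplitude_deg=8.0, peak_speed_deg_s=300.0),
        heading_deg=heading)


class TestBinning:
    def test_homogeneous_train_gives_flat_bins(self, rng):
        rate = 10.0
        duration = 400_000.0
        spikes = np.sort(rng.uniform(0, duration, int(rate * duration / 1000.0)))
        snippets = [make_snippet(1000.0 + 1500.0 * i) for i in range(250)]
        binned = bin_perisaccadic_rates(spikes, snippets)
        # binomial tolerance: each bin averages 250 snippets x 20 ms
        sem = np.sqrt(rate / (250 * 0.02))
        assert np.all(np.abs(binned.rates[0.0] - rate) < 4 * sem)

    def test_empty_spike_train_gives_zero_bins(self):
        binned = bin_perisaccadic_rates(np.array([]), [make_snippet(500.0)])
        assert np.all(binned.rates[0.0] == 0.0)

    def test_single_spike_lands_in_its_bin_at_50_hz(self):
        binned = bin_perisaccadic_rates(np.array([510.0]), [make_snippet(500.0)])
        rates = binned.rates[0.0]
        j = np.flatnonzero(binned.bin_left_ms == 0.0)[0]
        assert rates[j] == pytest.approx(50.0)  # 1 spike / 20 ms
        assert np.sum(rates != 0.0) == 1

    def test_rates_invariant_to_snippet_order(self, rng):
        spikes = np.sort(rng.uniform(0, 60_000.0, 600))
        snippets = [make_snippet(1000.0 + 1200.0 * i, heading=30.0)
                    for i in range(40)]
        a = bin_perisaccadic_rates(spikes, snippets)
        b = bin_perisaccadic_rates(spikes, snippets[::-1])
        assert np.array_equal(a.rates[30.0], b.rates[30.0])

    def test_bin_grid_is_33_twenty_ms_bins(self):
        edges = bin_left_edges()
        assert edges.size == 33
        assert edges[0] == -200.0 and edges[-1] == 440.0
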