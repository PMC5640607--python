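import numpy as np
import pandas as pd
import pytest

from perisacc.decoding import CompressionCurve
from perisacc.psychophysics import (behavioral_compression,
                                    cross_correlate_compression,
                                    discrimination_dprime, dprime_pooled,
                                    perceived_timecourse,
                                    reference_frame_analysis, running_mean)
from perisacc.synthetic import (BehavioralGenParams,
                                gaussian_compression_profile,
                                generate_behavioral_trials,
                                generate_discrimination_trials)


def make_curve(center_ms=110.0, depth=0.7, t0=-200.0, t1=450.0, step=20.0):
    t = np.arange(t0, t1 + step / 2, step)
    v = 1.0 - depth * np.exp(-0.5 * ((t - center_ms) / 50.0) ** 2)
    return CompressionCurve(t, v, ((-200, -100), (200, 300)), center_ms, False)


class TestPerceivedTimecourse:
    def test_running_mean_of_five(self):
        assert running_mean(np.array([10, 20, 30, 20, 10.0]))[2] == 18.0

    def test_veridical_reports_give_flat_series(self):
        p = BehavioralGenParams(compression_profile=lambda t: np.zeros_like(np.asarray(t, float)),
                                report_noise_sd=0.0, central_bias=0.0)
        series, _ = perceived_timecourse(generate_behavioral_trials(p, seed=0))
        for h, s in series.items():
            assert np.allclose(s.smoothed_deg, h)

    def test_compressed_trials_dip_toward_zero_near_onset(self):
        p = BehavioralGenParams(
            compression_profile=gaussian_compression_profile(peak=1.0),
            report_noise_sd=0.0)
        series, _ = perceived_timecourse(generate_behavioral_trials(p, seed=1))
        s = series[30.0]
        near = np.abs(s.onset_ms) < 10.0
        far = np.abs(s.onset_ms) > 150.0
        assert np.abs(s.smoothed_deg[near]).max() < 10.0
        assert np.abs(s.smoothed_deg[far]).min() > 20.0

    def test_too_few_trials_flagged_unsmoothed(self):
        trials = pd.DataFrame({
            "subject": ["S"] * 3, "condition": ["saccade"] * 3,
            "onset_ms": [-50.0, 0.0, 50.0], "true_heading_deg": [15.0] * 3,
            "reported_heading_deg": [14.0, 15.0, 16.0],
            "alpha_deg": [0.0] * 3, "head_deg": [0.0] * 3})
        series, _ = perceived_timecourse(trials)
        assert not series[15.0].smoothed_flag


class TestBehavioralCompression:
    def test_uncompressed_data_is_flat(self):
        p = BehavioralGenParams(compression_profile=lambda t: np.zeros_like(np.asarray(t, float)))
        series, _ = perceived_timecourse(generate_behavioral_trials(p, seed=4))
        comp = behavioral_compression(series)
        assert comp.is_flat
        assert comp.t_max_compression_ms is None

    def test_argmin_tracks_generator_peak_time(self):
        p = BehavioralGenParams(
            compression_profile=gaussian_compression_profile(peak=1.0,
                                                             center_ms=-5.0),
            report_noise_sd=0.0)
        series, _ = perceived_timecourse(generate_behavioral_trials(p, seed=5))
        comp = behavioral_compression(series)
        assert comp.t_max_compression_ms == pytest.approx(-5.0, abs=5.0)

    def test_subject_mean_argmin_matches_reported_band(self):
        """Generator matched to the reported mean profile: subject-mean peak
        compression between -10 and -1 ms relative to saccade onset."""
        argmins = []
        for s in range(8):
            p = BehavioralGenParams(
                compression_profile=gaussian_compression_profile(
                    peak=0.8, center_ms=-5.5))
            series, _ = perceived_timecourse(
                generate_behavioral_trials(p, seed=100 + s))
            argmins.append(behavioral_compression(series).t_max_compression_ms)
        assert -10.0 <= np.mean(argmins) <= -1.0


class TestDPrime:
    def test_identical_performance_gives_zero(self):
        assert dprime_pooled([0.97] * 20, [0.97] * 20).d_prime == 0.0

    def test_pooled_sd_arithmetic(self, rng):
        x1 = rng.normal(0.97, 0.1, 50)
        x2 = rng.normal(0.95, 0.1, 50)
        res = dprime_pooled(x1, x2)
        pooled = np.sqrt((49 * x1.std(ddof=1) ** 2 + 49 * x2.std(ddof=1) ** 2)
                         / 98)
        assert res.d_prime == pytest.approx((x1.mean() - x2.mean()) / pooled)
        assert res.combined_std == pytest.approx(pooled)

    def test_equal_sds_example_gives_point_two(self):
        """Means 0.97 vs 0.95 with SD 0.1 in both windows: d' = 0.2."""
        rng = np.random.default_rng(1)
        x1 = rng.normal(0, 1, 50)
        x1 = 0.97 + 0.1 * (x1 - x1.mean()) / x1.std(ddof=1)
        x2 = rng.normal(0, 1, 50)
        x2 = 0.95 + 0.1 * (x2 - x2.mean()) / x2.std(ddof=1)
        assert dprime_pooled(x1, x2).d_prime == pytest.approx(0.2, rel=1e-9)

    def test_antisymmetric_under_window_swap(self, rng):
        x1, x2 = rng.normal(0.9, 0.05, 30), rng.normal(0.8, 0.05, 30)
        assert dprime_pooled(x1, x2).d_prime == pytest.approx(
            -dprime_pooled(x2, x1).d_prime)

    def test_unequal_means_zero_sd_flagged_infinite(self):
        res = dprime_pooled([0.97] * 10, [0.95] * 10)
        assert res.infinite and np.isinf(res.d_prime)

    def test_no_deficit_generator_gives_small_dprime(self):
        ds = []
        for s in range(10):
            trials = generate_discrimination_trials(
                2000, p_correct_fixation=0.97, p_correct_perisaccadic=0.97,
                seed=s)
            ds.append(discrimination_dprime(trials)[0].d_prime)
        assert abs(np.mean(ds)) < 0.5

    def test_deficit_generator_reports_percent_correct(self):
        trials = generate_discrimination_trials(4000, seed=3)
        res, percents = discrimination_dprime(trials)
        assert percents["prepost"] > percents["peri"]
        assert res.d_prime > 0


class TestCrossCorrelation:
    def test_curve_against_itself_gives_zero_lag(self):
        c = make_curve()
        est = cross_correlate_compression(c, c)
        assert est.tau_ms == 0.0
        assert est.peak_correlation == pytest.approx(1.0)

    def test_shifted_curve_recovers_shift(self):
        neural = make_curve(center_ms=150.0)
        behav = make_curve(center_ms=110.0)
        est = cross_correlate_compression(neural, behav)
        assert est.tau_ms == 40.0

    @pytest.mark.parametrize("delta", [-60.0, -20.0, 0.0, 40.0, 80.0])
    def test_injected_lag_recovered_within_grid_step(self, delta):
        neural = make_curve(center_ms=110.0 + delta)
        behav = make_curve(center_ms=110.0, t0=-300.0, t1=550.0)
        est = cross_correlate_compression(neural, behav)
        assert abs(est.tau_ms - delta) <= 20.0

    def test_flat_curve_rejected(self):
        t = np.arange(-200.0, 451.0, 20.0)
        flat = CompressionCurve(t, np.ones_like(t), ((-200, -100), (200, 300)),
                                None, True)
        with pytest.raises(ValueError):
            cross_correlate_compression(flat, make_curve())


class TestReferenceFrame:
    @staticmethod
    def trials(gaze=0.0, head=0.0, seed=0):
        p = BehavioralGenParams(
            compression_profile=gaussian_compression_profile(peak=1.0),
            gaze_offset=gaze, head_offset=head, report_noise_sd=2.0)
        return generate_behavioral_trials(p, seed=seed)

    def test_gaze_offset_condition_classified_as_gaze_centered(self):
        res = reference_frame_analysis({
            "head_offset": self.trials(head=-15.0, seed=1),
            "gaze_offset": self.trials(gaze=-15.0, seed=2)})
        assert res.classified == "D_gaze"
        assert res.centers["gaze_offset"] == pytest.approx(-15.0, abs=3.0)
        assert res.centers["head_offset"] == pytest.approx(0.0, abs=3.0)

    def test_head_offset_alone_rules_out_head_centering(self):
        res = reference_frame_analysis({
            "head_offset": self.trials(head=-15.0, seed=3)})
        assert res.classified != "A_head"

    def test_no_offsets_is_degenerate(self):
        res = reference_frame_analysis({"main": self.trials(seed=4)})
        assert res.classified == "indistinguishable"
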