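import numpy as np
import pytest

from perisacc.decoding import running_mean2
from perisacc.eye_events import window_mask
from perisacc.kernels import default_kernels
from perisacc.modulation import (assign_conditions, bootstrap_ci,
                                 extract_kernel, extract_kernels,
                                 index_sign_tests, modulation_index,
                                 response_modulation, sign_test_median)
from perisacc.tuning import TuningFit


class TestResponseModulation:
    def test_constant_rate_modulates_to_zero(self):
        assert np.allclose(response_modulation(np.full(33, 10.0)), 0.0)

    def test_single_silent_bin_arithmetic(self):
        rates = np.full(33, 10.0)
        rates[10] = 0.0
        mod = response_modulation(rates)
        assert mod[10] == pytest.approx(-10.0 * 32 / 33)   # about -9.7
        assert mod[0] == pytest.approx(10.0 / 33)          # about +0.3

    def test_modulation_sums_to_zero(self, rng):
        mod = response_modulation(rng.uniform(0, 40, 33))
        assert mod.sum() == pytest.approx(0.0, abs=1e-9)


class TestBootstrapCI:
    def test_identical_neurons_zero_width(self, bins):
        courses = np.tile(np.linspace(0, 1, 33), (8, 1))
        tc = bootstrap_ci(courses, bins, seed=0)
        assert np.allclose(tc.ci_low, tc.ci_high)

    def test_same_seed_same_interval(self, bins, rng):
        courses = rng.normal(0, 1, (20, 33))
        a = bootstrap_ci(courses, bins, seed=7)
        b = bootstrap_ci(courses, bins, seed=7)
        assert np.array_equal(a.ci_low, b.ci_low)
        assert np.array_equal(a.ci_high, b.ci_high)

    def test_coverage_of_true_mean_near_95_percent(self):
        """Percentile-bootstrap CI covers the true mean ~95% of the time."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 200
        for _ in range(reps):
            sample = rng.normal(0.0, 1.0, (71, 1))
            tc = bootstrap_ci(sample, np.array([0.0]), n_boot=500, seed=rng)
            hits += tc.ci_low[0] <= 0.0 <= tc.ci_high[0]
        assert 0.90 <= hits / reps <= 0.99

    def test_small_n_boot_warns(self, bins, rng):
        with pytest.warns(UserWarning):
            bootstrap_ci(rng.normal(0, 1, (5, 33)), bins, n_boot=50, seed=0)


class TestAssignConditions:
    def make(self, slopes):
        fits = [TuningFit(s, 10.0, 0.9, 0.01) for s in slopes]
        resp = [{-30.0: np.full(33, 100.0 + i), 30.0: np.full(33, 200.0 + i)}
                for i in range(len(slopes))]
        return fits, resp

    def test_left_tuned_neuron_assignment(self):
        fits, resp = self.make([-0.2])
        cong, incong, kept = assign_conditions(fits, resp)
        assert np.all(cong == 100.0) and np.all(incong == 200.0)

    def test_right_tuned_neuron_reversed(self):
        fits, resp = self.make([+0.2])
        cong, incong, _ = assign_conditions(fits, resp)
        assert np.all(cong == 200.0) and np.all(incong == 100.0)

    def test_each_neuron_contributes_to_both_conditions(self):
        fits, resp = self.make([-0.2, 0.3, -1.0, 0.5, 0.0])
        cong, incong, kept = assign_conditions(fits, resp)
        assert cong.shape[0] == incong.shape[0] == 4  # zero slope dropped
        assert kept == [0, 1, 2, 3]


class TestModulationIndex:
    def test_flat_response_has_unit_index(self, bins):
        assert modulation_index(np.full(33, 12.0), bins) == pytest.approx(1.0)

    def test_halved_perisaccadic_rate(self, bins):
        rates = np.full(33, 12.0)
        rates[window_mask(bins, 40.0, 160.0)] *= 0.5
        assert modulation_index(rates, bins) == pytest.approx(0.5)

    def test_zero_late_rate_flagged_nan(self, bins):
        rates = np.zeros(33)
        rates[0] = 5.0
        assert np.isnan(modulation_index(rates, bins))

    def test_applied_gain_recovered_as_median_index(self, bins, rng):
        """Gain g in [40,160) ms recovers as the median index across
        Poisson-noisy neurons (50 replicates)."""
        g = 0.6
        medians = []
        for _ in range(50):
            idx = []
            for _n in range(30):
                base = rng.poisson(15.0 * 0.02 * 60, 33) / (0.02 * 60)
                rates = base.astype(float)
                rates[window_mask(bins, 40.0, 160.0)] *= g
                idx.append(modulation_index(rates, bins))
            medians.append(np.median(idx))
        assert np.median(medians) == pytest.approx(g, abs=0.05)


class TestSignTests:
    def test_all_unit_indices_give_no_evidence(self):
        res = sign_test_median(np.ones(20), "less", seed=0)
        assert res.p_value == 1.0

    def test_twenty_suppressed_indices_significant(self):
        res = sign_test_median(np.full(20, 0.8), "less", seed=0)
        assert res.median == pytest.approx(0.8)
        assert res.p_value == pytest.approx(0.5**20, rel=1e-9)

    def test_paired_conditions_tested_in_opposite_directions(self):
        out = index_sign_tests(np.full(10, 0.7), np.full(10, 1.3), seed=0)
        assert out["congruent"].p_value < 0.05
        assert out["incongruent"].p_value < 0.05


class TestKernelExtraction:
    def test_flat_rate_gives_unit_gain(self, bins):
        k = extract_kernel(bins + 10.0, np.full(33, 20.0), "global")
        assert np.allclose(k.gain, 1.0)

    def test_fifty_percent_dip_recovered(self, bins):
        rates = np.full(33, 20.0)
        dip = window_mask(bins, 60.0, 100.0)
        rates[dip] = 10.0
        k = extract_kernel(bins + 10.0, rates, "congruent")
        assert np.allclose(k.gain[dip], 0.5)
        assert k.flank_mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_flank_mean_rejected(self, bins):
        with pytest.raises(ValueError):
            extract_kernel(bins + 10.0, np.zeros(33), "global")

    def test_condition_matrices_yield_three_normalized_kernels(self, bins, rng):
        cong = 15.0 + rng.normal(0, 1, (10, 33))
        incong = 10.0 + rng.normal(0, 1, (10, 33))
        ks = extract_kernels(bins + 10.0, cong, incong)
        assert set(ks) == {"congruent", "incongruent", "global"}
        for k in ks.values():
            assert k.flank_mean() == pytest.approx(1.0, abs=1e-9)


def test_enhancement_peak_follows_suppression_peak(bins):
    """With the 40 ms generative offset, the incongruent enhancement peaks
    after the congruent suppression on the running-mean grid."""
    ks = default_kernels()
    centers = bins + 10.0
    cong_rate = 15.0 * ks["congruent"](centers)
    incong_rate = 9.0 * ks["incongruent"](centers)
    t_c, v_c = running_mean2(centers, cong_rate)
    t_i, v_i = running_mean2(centers, incong_rate)
    t_supp = t_c[np.argmin(v_c)]
    t_enh = t_i[np.argmax(v_i)]
    assert t_supp == pytest.approx(80.0, abs=20.0)
    assert t_enh == pytest.approx(120.0, abs=20.0)
    assert t_enh > t_supp
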