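"""Synthetic data with the statistical structure the analyses assume.

Three generators stand in for the recorded data set:

* optokinetic-like eye traces — alternating constant-velocity slow phases
  and brief, high-speed resetting saccades with a minimum-jerk profile —
  together with ground-truth saccade onsets for validating the detector;
* linearly heading-tuned spiking populations with perisaccadic
  multiplicative gain modulation and Poisson spike generation;
* behavioral heading-report trial sets with central bias, perisaccadic
  compression toward the direction of gaze, and report noise.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .eye_events import EyeTrace
from .kernels import SuppressionKernel, identity_kernel

#: minimum-jerk peak-speed factor: peak speed = 1.875 * amplitude / duration
_MINJERK_PEAK = 1.875


# ---------------------------------------------------------------------------
# eye traces


@dataclass
class OknParams:
    """Parameters of the optokinetic-like eye-movement generator.

    slow_phase_speed : deg/s
        Constant drift speed of the slow tracking phases.
    saccade_amplitude_mean, saccade_amplitude_sd : deg
        Resetting-saccade amplitude distribution; a mean of 0 disables
        saccades entirely (pure slow phase).
    saccade_peak_speed : deg/s
        Peak speed of the minimum-jerk saccade profile; must exceed the
        80 deg/s detection criterion.
    intersaccadic_interval_mean, min_intersaccadic_interval : ms
        Onset-to-onset intervals are a shifted exponential
        ``min + Exp(mean - min)`` so that long (> 650 ms) gaps, and hence
        isolation-eligible snippets, occur.
    sampling_rate : Hz
    recenter_gain : unitless
        Fraction of the pre-saccadic eccentricity corrected by each
        saccade; keeps the beating field near screen center.
    position_noise_sd : deg
        Optional white positional noise added to the sampled trace.
    """

    slow_phase_speed: float = 8.0
    saccade_amplitude_mean: float = 8.0
    saccade_amplitude_sd: float = 1.0
    saccade_peak_speed: float = 300.0
    intersaccadic_interval_mean: float = 1000.0
    min_intersaccadic_interval: float = 250.0
    sampling_rate: float = 500.0
    recenter_gain: float = 0.5
    position_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.saccade_amplitude_mean > 0 and self.saccade_peak_speed <= 80.0:
            raise ValueError("saccade_peak_speed must exceed the 80 deg/s "
                             "detection criterion")
        if self.intersaccadic_interval_mean <= self.min_intersaccadic_interval:
            raise ValueError("intersaccadic_interval_mean must exceed the "
                             "minimum interval")


@dataclass(frozen=True)
class TrueSaccade:
    """Ground truth for one generated saccade."""

    start_ms: float
    duration_ms: float
    d_horiz_deg: float
    d_vert_deg: float

    @property
    def amplitude_deg(self) -> float:
        return math.hypot(self.d_horiz_deg, self.d_vert_deg)

    @property
    def peak_speed_deg_s(self) -> float:
        return _MINJERK_PEAK * self.amplitude_deg / (self.duration_ms / 1000.0)

    def threshold_crossing_ms(self, threshold_deg_s: float = 80.0) -> float:
        """Time (ms) at which the ideal speed profile first reaches threshold.

        The minimum-jerk speed is ``v(tau) = 30 A/D tau^2 (1-tau)^2``; the
        first crossing solves a quadratic in ``tau (1 - tau)``.
        """
        c = threshold_deg_s * (self.duration_ms / 1000.0) / (30.0 * self.amplitude_deg)
        root = math.sqrt(c)
        if 4.0 * root > 1.0:
            raise ValueError("saccade never reaches the requested threshold")
        tau = (1.0 - math.sqrt(1.0 - 4.0 * root)) / 2.0
        return self.start_ms + tau * self.duration_ms


def _minjerk_position(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_eye_trace(params: OknParams, duration_s: float,
                       seed: int | np.random.Generator = 0,
                       ) -> tuple[EyeTrace, list[TrueSaccade]]:
    """Simulate an optokinetic-like eye trace.

    Returns the sampled trace and the ground-truth saccade list (empty if
    ``saccade_amplitude_mean`` is 0).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1000.0 / params.sampling_rate
    duration_ms = duration_s * 1000.0
    n = int(round(duration_ms / dt)) + 1
    t = np.arange(n) * dt

    v = params.slow_phase_speed
    x = v * t / 1000.0
    y = 0.8 * np.sin(2 * np.pi * t / 9000.0 + rng.uniform(0, 2 * np.pi))

    saccades: list[TrueSaccade] = []
    if params.saccade_amplitude_mean > 0:
        drift_sign = float(np.sign(v)) if v != 0 else 1.0
        t_k = params.min_intersaccadic_interval + rng.exponential(
            params.intersaccadic_interval_mean - params.min_intersaccadic_interval)
        x_offset = 0.0
        while True:
            amp = max(0.5, rng.normal(params.saccade_amplitude_mean,
                                      params.saccade_amplitude_sd))
            x_pre = v * t_k / 1000.0 + x_offset
            d_h = -(drift_sign * amp + params.recenter_gain * x_pre)
            d_v = rng.normal(0.0, 0.3)
            mag = math.hypot(d_h, d_v)
            dur = 1000.0 * _MINJERK_PEAK * mag / params.saccade_peak_speed
            if t_k + dur >= duration_ms:
                break
            sac = TrueSaccade(start_ms=t_k, duration_ms=dur,
                              d_horiz_deg=d_h, d_vert_deg=d_v)
            saccades.append(sac)
            prof = _minjerk_position((t - t_k) / dur)
            x = x + d_h * prof
            y = y + d_v * prof
            x_offset += d_h
            t_k = t_k + params.min_intersaccadic_interval + rng.exponential(
                params.intersaccadic_interval_mean
                - params.min_intersaccadic_interval)

    if params.position_noise_sd > 0:
        x = x + rng.normal(0.0, params.position_noise_sd, size=n)
        y = y + rng.normal(0.0, params.position_noise_sd, size=n)

    trace = EyeTrace(time_ms=t, horiz_deg=x, vert_deg=y,
                     sampling_rate_hz=params.sampling_rate)
    return trace, saccades


# ---------------------------------------------------------------------------
# spiking populations


@dataclass(frozen=True)
class VirtualNeuron:
    """A linearly heading-tuned model neuron.

    Mean rate at heading ``x`` is ``a * x + b`` (spikes/s), clamped at 0
    after gain and noise are applied — model neurons cannot have negative
    firing rates.
    """

    slope_a: float
    intercept_b: float
    noise_sd: float = 0.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.intercept_b < 0:
            raise ValueError("intercept_b must be non-negative")


def generate_population(n_negative: int = 38, n_positive: int = 33,
                        slope_median: float = 0.2, slope_log_sd: float = 0.5,
                        intercept_median: float = 10.0,
                        intercept_log_sd: float = 0.4,
                        noise_sd: float = 2.0,
                        seed: int | np.random.Generator = 0,
                        ) -> list[VirtualNeuron]:
    """Draw a heading-tuned population (default 38 left- and 33 right-tuned).

    Slope magnitudes and intercepts are log-normal; medians default to
    0.2 (sp/s)/deg and 10 sp/s, i.e. a ~12 sp/s tuning span over +/-30 deg
    on a ~10 sp/s baseline.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = n_negative + n_positive
    mags = rng.lognormal(math.log(slope_median), slope_log_sd, size=n)
    signs = np.r_[-np.ones(n_negative), np.ones(n_positive)]
    intercepts = rng.lognormal(math.log(intercept_median), intercept_log_sd, size=n)
    return [VirtualNeuron(slope_a=float(s * m), intercept_b=float(b),
                          noise_sd=noise_sd)
            for s, m, b in zip(signs, mags, intercepts)]


def _resolve_kernel(kernel_assignment, idx: int,
                    neuron: VirtualNeuron) -> SuppressionKernel | None:
    if kernel_assignment is None:
        return None
    if isinstance(kernel_assignment, SuppressionKernel):
        return kernel_assignment
    if isinstance(kernel_assignment, dict):
        return kernel_assignment.get(idx)
    return kernel_assignment(idx, neuron)


def generate_spike_trains(population: Sequence[VirtualNeuron], heading_deg: float,
                          saccade_onsets_ms: Sequence[float],
                          kernel_assignment=None,
                          duration_s: float = 10.0,
                          seed: int | np.random.Generator = 0,
                          dt_ms: float = 1.0) -> list[np.ndarray]:
    """Draw spike trains from gain-modulated linear heading tuning.

    The instantaneous rate of neuron i is
    ``max(0, gain_i(t) * (a_i * heading + b_i) + noise)`` where ``gain_i``
    multiplies the neuron's kernel at every saccade onset.
    ``kernel_assignment`` may be None (identity), a single kernel, a dict
    ``index -> kernel``, or a callable ``(index, neuron) -> kernel``.
    Returns one sorted spike-time array (ms) per neuron.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_t = int(round(duration_s * 1000.0 / dt_ms))
    t = np.arange(n_t) * dt_ms
    onsets = np.asarray(saccade_onsets_ms, dtype=float)

    gain_cache: dict[int, np.ndarray] = {}

    def gain_timeline(kernel: SuppressionKernel | None) -> np.ndarray:
        if kernel is None:
            return np.ones(n_t)
        key = id(kernel)
        if key not in gain_cache:
            g = np.ones(n_t)
            for onset in onsets:
                rel = t - onset
                sel = (rel >= kernel.time_ms[0]) & (rel <= kernel.time_ms[-1])
                g[sel] *= kernel(rel[sel])
            gain_cache[key] = g
        return gain_cache[key]

    trains: list[np.ndarray] = []
    for idx, neuron in enumerate(population):
        g = gain_timeline(_resolve_kernel(kernel_assignment, idx, neuron))
        rate = g * (neuron.slope_a * heading_deg + neuron.intercept_b)
        if neuron.noise_sd > 0:
            # slow rate noise, constant over 20 ms blocks
            n_blocks = n_t * dt_ms / 20.0
            blocks = rng.normal(0.0, neuron.noise_sd, size=int(math.ceil(n_blocks)))
            rate = rate + np.repeat(blocks, int(round(20.0 / dt_ms)))[:n_t]
        rate = np.maximum(rate, 0.0)
        counts = rng.poisson(rate * dt_ms / 1000.0)
        reps = np.repeat(t, counts)
        spikes = reps + rng.uniform(0.0, dt_ms, size=reps.size)
        trains.append(np.sort(spikes))
    return trains


# ---------------------------------------------------------------------------
# behavioral trials


def gaussian_compression_profile(peak: float = 0.8, center_ms: float = 0.0,
                                 sd_ms: float = 50.0) -> Callable[[float], float]:
    """Gaussian-in-time compression gain, ``c(t) in [0, 1]``.

    ``c = 1`` means full compression of the percept to the gaze center,
    ``c = 0`` no compression. The profile peaks at ``center_ms`` relative
    to saccade onset.
    """
    if not 0.0 <= peak <= 1.0:
        raise ValueError("peak must lie in [0, 1]")

    def profile(t_ms):
        return peak * np.exp(-0.5 * ((np.asarray(t_ms, dtype=float) - center_ms)
                                     / sd_ms) ** 2)

    return profile


@dataclass
class BehavioralGenParams:
    """Parameters of the behavioral heading-report generator.

    ``compression_profile`` maps stimulus-onset time (ms relative to
    saccade onset) to a compression gain in [0, 1]. ``central_bias`` is
    the inward report displacement, in degrees, of the most eccentric
    heading; intermediate headings shift proportionally. ``gaze_offset``
    (alpha) shifts the center of compression with the eyes; a pure head
    offset does not.
    """

    headings: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    trials_per_heading: int = 200
    fixation_trials_per_heading: int = 50
    compression_profile: Callable[[float], float] | None = None
    central_bias: float = 0.0
    report_noise_sd: float = 3.0
    gaze_offset: float = 0.0
    head_offset: float = 0.0
    onset_jitter_ms: float = 200.0
    subject: str = "S01"

    def __post_init__(self) -> None:
        if len(self.headings) == 0:
            raise ValueError("headings list must not be empty")
        if self.compression_profile is None:
            self.compression_profile = gaussian_compression_profile()


#: column order of behavioral trial tables
TRIAL_COLUMNS = ["subject", "condition", "onset_ms", "true_heading_deg",
                 "reported_heading_deg", "alpha_deg", "head_deg"]


def generate_behavioral_trials(params: BehavioralGenParams,
                               seed: int | np.random.Generator = 0,
                               ) -> pd.DataFrame:
    """Generate a behavioral trial table.

    Reported heading is
    ``gaze + (1 - c(t)) * (heading_in_gaze_coords + bias) + noise`` where
    the gaze center is ``gaze_offset`` and ``c`` is the compression
    profile (0 in fixation trials). Stimulus onsets are uniform over
    ``+/- onset_jitter_ms``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h_max = max(abs(h) for h in params.headings)
    rows = []
    for condition, n_trials in (("saccade", params.trials_per_heading),
                                ("fixation", params.fixation_trials_per_heading)):
        for h in params.headings:
            onsets = rng.uniform(-params.onset_jitter_ms, params.onset_jitter_ms,
                                 size=n_trials)
            c = (np.asarray(params.compression_profile(onsets), dtype=float)
                 if condition == "saccade" else np.zeros(n_trials))
            h_gaze = h - params.gaze_offset
            bias = -params.central_bias * (h_gaze / h_max if h_max > 0 else 0.0)
            noise = (rng.normal(0.0, params.report_noise_sd, size=n_trials)
                     if params.report_noise_sd > 0 else np.zeros(n_trials))
            reports = params.gaze_offset + (1.0 - c) * (h_gaze + bias) + noise
            for onset, rep in zip(onsets, reports):
                rows.append((params.subject, condition, float(onset), float(h),
                             float(rep), params.gaze_offset, params.head_offset))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_discrimination_trials(n_trials: int = 2000,
                                   p_correct_fixation: float = 0.971,
                                   p_correct_perisaccadic: float = 0.961,
                                   peri_halfwidth_ms: float = 50.0,
                                   onset_jitter_ms: float = 200.0,
                                   subjects: int = 5,
                                   seed: int | np.random.Generator = 0,
                                   ) -> pd.DataFrame:
    """Forward/backward 2-AFC control trials with a perisaccadic deficit.

    Each trial is correct with probability ``p_correct_perisaccadic`` when
    the stimulus onset falls within ``peri_halfwidth_ms`` of saccade onset
    and ``p_correct_fixation`` otherwise.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    onsets = rng.uniform(-onset_jitter_ms, onset_jitter_ms, size=n_trials)
    peri = np.abs(onsets) < peri_halfwidth_ms
    p = np.where(peri, p_correct_perisaccadic, p_correct_fixation)
    correct = rng.random(n_trials) < p
    subj = [f"S{1 + i % subjects:02d}" for i in range(n_trials)]
    return pd.DataFrame({"subject": subj, "onset_ms": onsets,
                         "correct": correct.astype(int)})
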