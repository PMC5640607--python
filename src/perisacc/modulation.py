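"""Perisaccadic response modulation: time courses, indices, and kernels.

The modulation of a neuron is its binned perisaccadic rate minus the mean
rate over the full [-200, 450] ms window. Population time courses carry
bootstrap confidence intervals (resampling neurons). Each neuron
contributes its preferred-heading response to the congruent condition and
its anti-preferred response to the incongruent condition. The modulation
index is the ratio of the perisaccadic (40-160 ms) to the late
post-saccadic (300-450 ms) rate: below 1 = suppression, above 1 =
enhancement. Condition time courses, flank-normalized, yield the
multiplicative gain kernels used by the virtual-population model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .eye_events import window_mask
from .kernels import SuppressionKernel
from .tuning import TuningFit

INDEX_WINDOW_MS = (40.0, 160.0)
LATE_WINDOW_MS = (300.0, 450.0)


def response_modulation(rates: np.ndarray) -> np.ndarray:
    """Per-bin rate minus the full-window mean rate (sums to ~0)."""
    r = np.asarray(rates, dtype=float)
    return r - r.mean()


@dataclass
class ModulationTimecourse:
    time_ms: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    condition: str = "all"
    n_neurons: int = 0


def bootstrap_ci(per_neuron_courses: np.ndarray, time_ms: np.ndarray,
                 n_boot: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0,
                 condition: str = "all") -> ModulationTimecourse:
    """Mean time course across neurons with a percentile bootstrap CI.

    Neurons (rows) are resampled with replacement ``n_boot`` times; the CI
    is the percentile interval of the resampled means per bin.
    """
    courses = np.asarray(per_neuron_courses, dtype=float)
    if courses.ndim != 2 or courses.shape[0] < 2:
        raise ValueError("need a 2-D (neurons x bins) array with >= 2 neurons")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable confidence intervals",
                      stacklevel=2)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = courses.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = courses[idx].mean(axis=1)  # (n_boot, bins)
    lo_q = (1.0 - level) / 2.0
    return ModulationTimecourse(
        time_ms=np.asarray(time_ms, dtype=float),
        mean=courses.mean(axis=0),
        ci_low=np.quantile(boot_means, lo_q, axis=0),
        ci_high=np.quantile(boot_means, 1.0 - lo_q, axis=0),
        condition=condition, n_neurons=n)


def assign_conditions(fits, responses_per_heading,
                      left_heading: float = -30.0, right_heading: float = 30.0,
                      ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Split each tuned neuron's responses into congruent and incongruent.

    ``responses_per_heading`` is a sequence (one entry per neuron, aligned
    with ``fits``) of dicts heading -> binned rate array. A left-tuned
    neuron (slope < 0) contributes its leftward response to the congruent
    set and its rightward response to the incongruent set; right-tuned
    neurons the reverse. Zero-slope neurons are excluded. Returns
    ``(congruent, incongruent, kept_indices)`` with one row per kept
    neuron in each array.
    """
    cong, incong, kept = [], [], []
    for i, (fit, resp) in enumerate(zip(fits, responses_per_heading)):
        if fit.slope_a == 0:
            continue
        preferred = left_heading if fit.slope_a < 0 else right_heading
        anti = right_heading if fit.slope_a < 0 else left_heading
        cong.append(np.asarray(resp[preferred], dtype=float))
        incong.append(np.asarray(resp[anti], dtype=float))
        kept.append(i)
    if not kept:
        raise ValueError("no neuron with nonzero tuning slope")
    return np.vstack(cong), np.vstack(incong), kept


def modulation_index(rates: np.ndarray, bin_left_ms: np.ndarray,
                     index_window_ms=INDEX_WINDOW_MS,
                     late_window_ms=LATE_WINDOW_MS) -> float:
    """Ratio of perisaccadic to late post-saccadic mean rate.

    Returns NaN (neuron flagged undefined) when the late-window rate is 0.
    """
    r = np.asarray(rates, dtype=float)
    bins = np.asarray(bin_left_ms, dtype=float)
    peri = r[window_mask(bins, *index_window_ms)]
    late = r[window_mask(bins, *late_window_ms)]
    if peri.size == 0 or late.size == 0:
        raise ValueError("index windows select no bins")
    if late.mean() == 0:
        return float("nan")
    return float(peri.mean() / late.mean())


@dataclass
class SignTestResult:
    median: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    alternative: str


def sign_test_median(indices, alternative: str, null: float = 1.0,
                     n_boot: int = 1000, level: float = 0.95,
                     seed: int | np.random.Generator = 0) -> SignTestResult:
    """One-sided sign test of the median index against ``null``.

    ``alternative`` is "less" (suppression: median below null) or
    "greater" (enhancement). The CI is a percentile bootstrap of the
    median. Values equal to the null are uninformative and dropped from
    the test.
    """
    x = np.asarray(indices, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite indices")
    if alternative == "less":
        k = int(np.sum(x < null))
    elif alternative == "greater":
        k = int(np.sum(x > null))
    else:
        raise ValueError("alternative must be 'less' or 'greater'")
    n_eff = int(np.sum(x != null))
    p = (1.0 if n_eff == 0
         else stats.binomtest(k, n_eff, 0.5, alternative="greater").pvalue)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    boot = np.median(x[rng.integers(0, x.size, size=(n_boot, x.size))], axis=1)
    lo_q = (1.0 - level) / 2.0
    return SignTestResult(median=float(np.median(x)), p_value=float(p),
                          ci_low=float(np.quantile(boot, lo_q)),
                          ci_high=float(np.quantile(boot, 1.0 - lo_q)),
                          n=int(x.size), alternative=alternative)


def index_sign_tests(congruent_indices, incongruent_indices,
                     seed: int | np.random.Generator = 0,
                     ) -> dict[str, SignTestResult]:
    """Sign tests of the condition medians: congruent below 1, incongruent above."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return {"congruent": sign_test_median(congruent_indices, "less", seed=rng),
            "incongruent": sign_test_median(incongruent_indices, "greater",
                                            seed=rng)}


def extract_kernel(time_ms: np.ndarray, mean_rates: np.ndarray,
                   label: str) -> SuppressionKernel:
    """Flank-normalize a raw-rate time course into a gain kernel.

    The input must be in rate units (not mean-subtracted); the gain is
    rate divided by the mean rate more than 100 ms away from the saccade.
    """
    kernel = SuppressionKernel(np.asarray(time_ms, dtype=float),
                               np.asarray(mean_rates, dtype=float), label=label)
    if kernel.flank_mean() <= 0:
        raise ValueError("zero flank-mean rate: cannot form a gain kernel")
    return kernel.normalized()


def extract_kernels(time_ms: np.ndarray, congruent: np.ndarray,
                    incongruent: np.ndarray) -> dict[str, SuppressionKernel]:
    """Global, congruent and incongruent kernels from condition matrices.

    ``congruent`` and ``incongruent`` are (neurons x bins) raw-rate
    arrays; the global kernel comes from the all-response mean.
    """
    cong = np.asarray(congruent, dtype=float).mean(axis=0)
    incong = np.asarray(incongruent, dtype=float).mean(axis=0)
    glob = (cong + incong) / 2.0
    return {"congruent": extract_kernel(time_ms, cong, "congruent"),
            "incongruent": extract_kernel(time_ms, incong, "incongruent"),
            "global": extract_kernel(time_ms, glob, "global")}
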