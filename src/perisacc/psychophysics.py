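"""Behavioral heading-perception analyses.

Perceived-heading time courses (5-point running means over trials sorted
by stimulus-onset time), the behavioral compression statistic, the
forward/backward discrimination control with its pooled-SD effect size
d', the cross-correlation latency between neural and behavioral
compression curves, and the reference-frame classification of the
compression center (head / body / screen / gaze).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import CompressionCurve


# ---------------------------------------------------------------------------
# perceived-heading time courses


@dataclass
class HeadingSeries:
    """Reports for one heading, sorted by onset, with a running mean."""

    heading_deg: float
    onset_ms: np.ndarray
    reported_deg: np.ndarray
    smoothed_deg: np.ndarray
    smoothed_flag: bool  # False when too few trials for the running mean


def running_mean(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered k-point running mean with truncated edge windows."""
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(k, center=True, min_periods=1).mean().to_numpy()


def perceived_timecourse(trials: pd.DataFrame, k: int = 5,
                         ) -> tuple[dict[float, HeadingSeries], dict[float, float]]:
    """Per-heading perceived-heading series and fixation reference means.

    ``trials`` uses the behavioral trial schema (condition "saccade" or
    "fixation"). Saccade trials are sorted by onset and smoothed with a
    centered ``k``-point running mean; headings with fewer than ``k``
    trials keep the raw series and are flagged. Returns
    ``(series_per_heading, fixation_mean_per_heading)``.
    """
    series: dict[float, HeadingSeries] = {}
    sacc = trials[trials["condition"] == "saccade"]
    for h, grp in sacc.groupby("true_heading_deg"):
        grp = grp.sort_values("onset_ms")
        reports = grp["reported_heading_deg"].to_numpy()
        enough = reports.size >= k
        series[float(h)] = HeadingSeries(
            heading_deg=float(h),
            onset_ms=grp["onset_ms"].to_numpy(),
            reported_deg=reports,
            smoothed_deg=running_mean(reports, k) if enough else reports.copy(),
            smoothed_flag=enough)
    fix = trials[trials["condition"] == "fixation"]
    fixation_means = {float(h): float(g["reported_heading_deg"].mean())
                      for h, g in fix.groupby("true_heading_deg")}
    return series, fixation_means


# ---------------------------------------------------------------------------
# behavioral compression


def _common_grid(series: dict[float, HeadingSeries],
                 grid_ms: float) -> np.ndarray:
    lo = max(s.onset_ms[0] for s in series.values())
    hi = min(s.onset_ms[-1] for s in series.values())
    if hi <= lo:
        raise ValueError("heading series do not overlap in time")
    return np.arange(lo, hi + grid_ms / 2.0, grid_ms)


def behavioral_compression(series: dict[float, HeadingSeries],
                           grid_ms: float = 2.5,
                           flank_ms: float = 100.0,
                           depth_threshold: float = 0.1) -> CompressionCurve:
    """Normalized across-heading SD of the perceived-heading series.

    The smoothed series are interpolated onto a common grid (default the
    ~2.5 ms trial spacing); the SD across headings is normalized by its
    mean at ``|t| >= flank_ms``. The argmin is reported as the time of
    maximum compression only when the curve dips more than
    ``depth_threshold`` below 1 (otherwise the curve is flagged flat).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 heading series")
    grid = _common_grid(series, grid_ms)
    stack = np.vstack([np.interp(grid, s.onset_ms, s.smoothed_deg)
                       for s in series.values()])
    sd = np.std(stack, axis=0, ddof=1)
    flank = (grid <= -flank_ms) | (grid >= flank_ms)
    if not flank.any():
        raise ValueError("no samples beyond the normalization flanks")
    norm = sd[flank].mean()
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("degenerate normalization: zero flank SD")
    nsd = sd / norm
    flat = bool(1.0 - nsd.min() < depth_threshold)
    t_min = None if flat else float(grid[int(np.argmin(nsd))])
    return CompressionCurve(time_ms=grid, normalized_sd=nsd,
                            norm_windows_ms=((-np.inf, -flank_ms),
                                             (flank_ms, np.inf)),
                            t_max_compression_ms=t_min, is_flat=flat)


# ---------------------------------------------------------------------------
# forward/backward discrimination control


@dataclass
class DPrimeResult:
    d_prime: float
    mean_prepost: float
    mean_peri: float
    n1: int
    n2: int
    std1: float
    std2: float
    combined_std: float
    infinite: bool = False


def dprime_pooled(sample_prepost, sample_peri) -> DPrimeResult:
    """Effect size d' = (mean_pre&post - mean_peri) / pooled SD.

    The pooled SD uses (n-1)-weighted variances. Equal means with zero
    pooled SD give d' = 0; unequal means with zero pooled SD are flagged
    infinite.
    """
    x1 = np.asarray(sample_prepost, dtype=float)
    x2 = np.asarray(sample_peri, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both windows must be non-empty")
    n1, n2 = x1.size, x2.size
    s1 = float(x1.std(ddof=1)) if n1 > 1 else 0.0
    s2 = float(x2.std(ddof=1)) if n2 > 1 else 0.0
    denom_df = n1 + n2 - 2
    pooled = (np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / denom_df)
              if denom_df > 0 else 0.0)
    diff = float(x1.mean() - x2.mean())
    scale = max(1.0, abs(x1.mean()), abs(x2.mean()))
    if pooled <= 1e-12 * scale:
        pooled = 0.0
    if abs(diff) <= 1e-12 * scale:
        diff = 0.0
    if pooled == 0:
        d = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
        return DPrimeResult(d_prime=d, mean_prepost=float(x1.mean()),
                            mean_peri=float(x2.mean()), n1=n1, n2=n2,
                            std1=s1, std2=s2, combined_std=0.0,
                            infinite=diff != 0)
    return DPrimeResult(d_prime=diff / pooled, mean_prepost=float(x1.mean()),
                        mean_peri=float(x2.mean()), n1=n1, n2=n2,
                        std1=s1, std2=s2, combined_std=float(pooled))


def discrimination_dprime(trials: pd.DataFrame,
                          peri_halfwidth_ms: float = 50.0,
                          ) -> tuple[DPrimeResult, dict[str, float]]:
    """Perisaccadic 2-AFC performance deficit.

    ``trials`` needs columns ``subject``, ``onset_ms``, ``correct``.
    Per-subject percent correct in the fixation-like (|t| > halfwidth)
    and perisaccadic (|t| < halfwidth) windows are the two samples of the
    pooled-SD d'. Returns the d' result and the overall percent correct
    per window.
    """
    peri_mask = trials["onset_ms"].abs() < peri_halfwidth_ms
    peri, prepost = trials[peri_mask], trials[~peri_mask]
    if peri.empty or prepost.empty:
        raise ValueError("both time windows must contain trials")
    perf_prepost = prepost.groupby("subject")["correct"].mean().to_numpy()
    perf_peri = peri.groupby("subject")["correct"].mean().to_numpy()
    result = dprime_pooled(perf_prepost, perf_peri)
    percents = {"prepost": float(prepost["correct"].mean() * 100.0),
                "peri": float(peri["correct"].mean() * 100.0)}
    return result, percents


# ---------------------------------------------------------------------------
# neural-behavioral latency


@dataclass
class LatencyEstimate:
    tau_ms: float
    peak_correlation: float


def cross_correlate_compression(neural: CompressionCurve,
                                behavioral: CompressionCurve,
                                lag_range_ms: tuple[float, float] = (-300.0, 300.0),
                                grid_ms: float = 20.0,
                                min_overlap: int = 5) -> LatencyEstimate:
    """Lag maximizing the correlation between two compression curves.

    Both curves are resampled onto a common ``grid_ms`` step; positive
    tau means the neural curve lags the behavioral one, i.e.
    ``neural(t) ~ behavioral(t - tau)``. Flat curves have no defined lag
    and are rejected.
    """
    def resample(curve: CompressionCurve):
        t = np.arange(curve.time_ms[0], curve.time_ms[-1] + grid_ms / 2.0,
                      grid_ms)
        return t, np.interp(t, curve.time_ms, curve.normalized_sd)

    tn, vn = resample(neural)
    tb, vb = resample(behavioral)
    if np.ptp(vn) < 1e-12 or np.ptp(vb) < 1e-12:
        raise ValueError("flat compression curve: lag undefined")
    lags = np.arange(np.ceil(lag_range_ms[0] / grid_ms),
                     np.floor(lag_range_ms[1] / grid_ms) + 1) * grid_ms
    best_tau, best_r = None, -np.inf
    for lag in lags:
        # neural(t) vs behavioral(t - lag): sample behavior at tn - lag
        shifted = tn - lag
        ok = (shifted >= tb[0]) & (shifted <= tb[-1])
        if ok.sum() < min_overlap:
            continue
        a = vn[ok]
        b = np.interp(shifted[ok], tb, vb)
        if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_tau, best_r = float(lag), r
    if best_tau is None:
        raise ValueError("no lag with sufficient overlap in the given range")
    return LatencyEstimate(tau_ms=best_tau, peak_correlation=best_r)


# ---------------------------------------------------------------------------
# reference frame of the compression center


@dataclass
class ReferenceFrameResult:
    centers: dict[str, float]          # observed center per condition
    t_max_compression: dict[str, float | None]
    predictions: dict[str, dict[str, float]]  # condition -> variant -> center
    classified: str                    # winning variant or "indistinguishable"
    mean_percept: dict[str, tuple[np.ndarray, np.ndarray]]


def _mean_percept_series(series: dict[float, HeadingSeries],
                         grid_ms: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    grid = _common_grid(series, grid_ms)
    stack = np.vstack([np.interp(grid, s.onset_ms, s.smoothed_deg)
                       for s in series.values()])
    return grid, stack.mean(axis=0)


def reference_frame_analysis(trials_by_condition: dict[str, pd.DataFrame],
                             grid_ms: float = 2.5,
                             tol_deg: float = 2.0) -> ReferenceFrameResult:
    """Classify the center of perisaccadic compression.

    ``trials_by_condition`` holds behavioral trial tables, typically
    ``{"head_offset": ..., "gaze_offset": ...}``, whose ``alpha_deg`` and
    ``head_deg`` columns state the gaze and head eccentricities. For each
    condition the across-heading mean percept at the time of maximum
    compression is the observed compression center. Candidate variants
    predict that center at: head midline (A) = head offset, body midline
    (B) = 0, screen center (C) = 0, gaze direction (D) = gaze offset. The
    variant minimizing the summed |observed - predicted| across
    conditions wins; if all predictions agree within ``tol_deg`` the
    conditions are reported as indistinguishable.
    """
    if not trials_by_condition:
        raise ValueError("need at least one condition")
    centers: dict[str, float] = {}
    t_marks: dict[str, float | None] = {}
    preds: dict[str, dict[str, float]] = {}
    mean_percepts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, trials in trials_by_condition.items():
        series, _ = perceived_timecourse(trials)
        comp = behavioral_compression(series, grid_ms=grid_ms)
        grid, mean_series = _mean_percept_series(series, grid_ms=grid_ms)
        mean_percepts[name] = (grid, mean_series)
        t_min = comp.t_max_compression_ms
        t_marks[name] = t_min
        if t_min is None:  # no compression: use the global mean as center
            centers[name] = float(mean_series.mean())
        else:
            centers[name] = float(np.interp(t_min, grid, mean_series))
        alpha = float(trials["alpha_deg"].iloc[0])
        head = float(trials["head_deg"].iloc[0])
        preds[name] = {"A_head": head, "B_body": 0.0, "C_screen": 0.0,
                       "D_gaze": alpha}
    variants = ["A_head", "B_body", "C_screen", "D_gaze"]
    spread = max(abs(preds[c][v] - preds[c][w]) for c in preds
                 for v in variants for w in variants)
    if spread <= tol_deg:
        classified = "indistinguishable"
    else:
        errors = {v: sum(abs(centers[c] - preds[c][v]) for c in preds)
                  for v in variants}
        classified = min(errors, key=errors.get)
    return ReferenceFrameResult(centers=centers, t_max_compression=t_marks,
                                predictions=preds, classified=classified,
                                mean_percept=mean_percepts)
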