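"""Per-neuron heading-tuning significance and linear tuning fits.

Tuning significance uses a rank one-way ANOVA (Kruskal-Wallis, 2 df for
three headings) on firing rates in 1000 ms trial slices. The tuning fit
is an ordinary least-squares line, rate = a * heading + b, through the
mean rates in a brief post-saccadic window (300-450 ms) — the decoder
later inverts this line, so near-zero slopes are flagged non-invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .eye_events import BinnedResponse, window_mask

#: slopes below this magnitude, (spikes/s)/deg, cannot be inverted sensibly
SLOPE_EPS = 1e-6

#: significance level of the rank ANOVA tuning filter
ALPHA = 0.05


@dataclass(frozen=True)
class TuningFit:
    """Linear heading tuning of one neuron: rate = slope_a * heading + intercept_b."""

    slope_a: float
    intercept_b: float
    r_squared: float
    p_fit: float
    p_anova: float | None = None

    @property
    def significant_tuning(self) -> bool:
        return self.p_anova is not None and self.p_anova < ALPHA

    @property
    def invertible(self) -> bool:
        return abs(self.slope_a) >= SLOPE_EPS


def heading_significance(slice_rates_per_heading) -> tuple[float, float]:
    """Kruskal-Wallis rank test across heading groups of slice rates.

    Returns ``(H, p)`` with the chi-square approximation (k-1 df,
    midrank ties). Groups of all-identical values across the board give
    ``H = 0, p = 1`` (no evidence of tuning).
    """
    groups = [np.asarray(g, dtype=float) for g in slice_rates_per_heading]
    if len(groups) < 2:
        raise ValueError("need at least 2 heading groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each heading group needs at least 2 slices")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def slice_rates(spike_times_ms: np.ndarray, duration_ms: float,
                slice_ms: float = 1000.0,
                exclude_intervals=None) -> np.ndarray:
    """Firing rate (spikes/s) in consecutive slices of a full trial.

    ``exclude_intervals`` optionally drops slices overlapping any
    ``(start_ms, stop_ms)`` interval (e.g. saccade flight times); by
    default all slices are kept.
    """
    spikes = np.asarray(spike_times_ms, dtype=float)
    n_slices = int(duration_ms // slice_ms)
    if n_slices < 1:
        raise ValueError("trial shorter than one slice")
    edges = slice_ms * np.arange(n_slices + 1)
    counts, _ = np.histogram(spikes, bins=edges)
    rates = counts / (slice_ms / 1000.0)
    if exclude_intervals:
        keep = np.ones(n_slices, dtype=bool)
        for start, stop in exclude_intervals:
            first = int(max(0, start // slice_ms))
            last = int(min(n_slices - 1, stop // slice_ms))
            if start < edges[-1] and stop > 0:
                keep[first:last + 1] = False
        rates = rates[keep]
    return rates


def fit_linear_tuning(post_rates, headings,
                      p_anova: float | None = None) -> TuningFit:
    """Least-squares line through (heading, mean post-saccadic rate) points.

    With identical rates at every heading the slope is 0 and the fit is
    flagged non-invertible (``r_squared = 0``, ``p_fit = 1``).
    """
    y = np.asarray(post_rates, dtype=float)
    x = np.asarray(headings, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (heading, rate) points")
    if np.ptp(y) == 0:
        return TuningFit(slope_a=0.0, intercept_b=float(y.mean()),
                         r_squared=0.0, p_fit=1.0, p_anova=p_anova)
    res = stats.linregress(x, y)
    return TuningFit(slope_a=float(res.slope), intercept_b=float(res.intercept),
                     r_squared=float(res.rvalue**2), p_fit=float(res.pvalue),
                     p_anova=p_anova)


def post_saccadic_rates(binned: BinnedResponse,
                        window_ms: tuple[float, float] = (300.0, 450.0),
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate per heading in the post-saccadic fit window.

    Returns ``(headings, rates)`` sorted by heading. The window selects
    bins by left edge, so (300, 450) covers the 300-460 ms tiling of the
    bin grid.
    """
    mask = window_mask(binned.bin_left_ms, *window_ms)
    headings = np.array(binned.headings())
    rates = np.array([binned.rates[h][mask].mean() for h in headings])
    return headings, rates


def fit_from_binned(binned: BinnedResponse,
                    window_ms: tuple[float, float] = (300.0, 450.0),
                    p_anova: float | None = None) -> TuningFit:
    headings, rates = post_saccadic_rates(binned, window_ms)
    return fit_linear_tuning(rates, headings, p_anova=p_anova)


def split_subpopulations(fits) -> tuple[int, int, int]:
    """Partition tuned neurons by slope sign.

    Returns ``(n_negative, n_positive, n_zero)``: left-tuned (a < 0),
    right-tuned (a > 0), and untuned-slope (a == 0) counts.
    """
    slopes = np.array([f.slope_a for f in fits])
    return (int(np.sum(slopes < 0)), int(np.sum(slopes > 0)),
            int(np.sum(slopes == 0)))
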