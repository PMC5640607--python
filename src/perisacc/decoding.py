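"""Inverse-regression heading decoding and the compression statistic.

Each neuron's binned rate y(t) is translated into a heading estimate by
inverting its tuning line, x(t) = (y(t) - b) / a; the population readout
is the median estimate per bin. Compression of the decoded headings is
quantified as the across-heading standard deviation over time, divided by
its mean in two 100 ms windows away from the saccade, so that 1 means "as
separated as during slow tracking" and 0 means full collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .eye_events import window_mask
from .tuning import TuningFit, heading_significance

#: normalization windows of the compression statistic, ms from saccade onset
NORM_WINDOWS_MS = ((-200.0, -100.0), (200.0, 300.0))


def decode_neuron(rates: np.ndarray, fit: TuningFit) -> np.ndarray:
    """Per-bin heading estimate (deg) from one neuron, x = (y - b) / a."""
    if not fit.invertible:
        raise ValueError("tuning slope too close to 0 to invert; exclude this "
                         "neuron upstream")
    return (np.asarray(rates, dtype=float) - fit.intercept_b) / fit.slope_a


def decode_population(per_neuron_series: np.ndarray) -> np.ndarray:
    """Median across neurons per bin (rows = neurons, columns = bins).

    NaN entries (neurons missing a bin) are dropped from that bin's
    median; bins with no valid neuron are NaN.
    """
    stack = np.asarray(per_neuron_series, dtype=float)
    if stack.ndim != 2 or stack.shape[0] < 1:
        raise ValueError("expected a 2-D (neurons x bins) array")
    with np.errstate(invalid="ignore"):
        return np.nanmedian(stack, axis=0)


@dataclass
class SeparationTest:
    """Per-bin rank-ANOVA separation of decoded headings with BH-FDR."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    tested: np.ndarray


def binwise_separation_test(decoded_per_heading: dict, alpha: float = 0.05,
                            ) -> SeparationTest:
    """Test, per bin, whether decoded headings differ across stimuli.

    ``decoded_per_heading`` maps heading to a (neurons x bins) array of
    per-neuron decoded values. A Kruskal-Wallis test is run per bin and
    Benjamini-Hochberg correction is applied across bins. Bins where any
    heading group has fewer than 2 finite values are excluded from
    testing and reported in ``tested``.
    """
    stacks = [np.asarray(v, dtype=float) for v in decoded_per_heading.values()]
    if len(stacks) < 2:
        raise ValueError("need at least 2 heading groups")
    n_bins = stacks[0].shape[1]
    p_raw = np.full(n_bins, np.nan)
    tested = np.zeros(n_bins, dtype=bool)
    for j in range(n_bins):
        groups = [s[:, j][np.isfinite(s[:, j])] for s in stacks]
        if any(g.size < 2 for g in groups):
            continue
        _, p = heading_significance(groups)
        p_raw[j] = p
        tested[j] = True
    p_adj = np.full(n_bins, np.nan)
    signif = np.zeros(n_bins, dtype=bool)
    if tested.any():
        rej, adj, _, _ = multipletests(p_raw[tested], alpha=alpha,
                                       method="fdr_bh")
        p_adj[tested] = adj
        signif[tested] = rej
    return SeparationTest(p_raw=p_raw, p_adjusted=p_adj, significant=signif,
                          tested=tested)


def running_mean2(times_ms: np.ndarray, values: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Average of consecutive bin pairs, stamped at the pair midpoint."""
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 bins")
    return (t[:-1] + t[1:]) / 2.0, (v[:-1] + v[1:]) / 2.0


@dataclass
class CompressionCurve:
    """Time-resolved normalized across-heading SD of decoded/perceived heading.

    ``time_ms`` stamps each value (bin centers for binned neural data);
    ``t_max_compression_ms`` is the time of the minimum, or None for a
    flat curve without a meaningful minimum.
    """

    time_ms: np.ndarray
    normalized_sd: np.ndarray
    norm_windows_ms: tuple
    t_max_compression_ms: float | None
    is_flat: bool

    @property
    def depth(self) -> float:
        """1 - min(normalized SD); 0 for a flat curve."""
        return float(1.0 - np.nanmin(self.normalized_sd))


def compression_curve(series_per_heading: dict, bin_left_ms: np.ndarray,
                      norm_windows_ms=NORM_WINDOWS_MS, bin_ms: float = 20.0,
                      flat_tol: float = 1e-9) -> CompressionCurve:
    """Across-heading SD of the raw decoded series, flank-normalized.

    The SD (ddof=1) across the heading series is divided by its mean over
    the normalization windows (bins selected by left edge); by
    construction that mean is 1 after normalization. The reported times
    are bin centers, and the compression maximum is the argmin of the
    normalized SD.
    """
    if len(series_per_heading) < 2:
        raise ValueError("need at least 2 heading series")
    stack = np.vstack([np.asarray(v, dtype=float)
                       for v in series_per_heading.values()])
    bin_left = np.asarray(bin_left_ms, dtype=float)
    if stack.shape[1] != bin_left.size:
        raise ValueError("series length does not match the bin grid")
    sd = np.std(stack, axis=0, ddof=1)
    mask = np.zeros(bin_left.size, dtype=bool)
    for w0, w1 in norm_windows_ms:
        mask |= window_mask(bin_left, w0, w1)
    norm = sd[mask].mean()
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("degenerate input: zero across-heading SD in the "
                         "normalization windows")
    nsd = sd / norm
    centers = bin_left + bin_ms / 2.0
    flat = bool(np.ptp(nsd) < flat_tol)
    t_min = None if flat else float(centers[int(np.argmin(nsd))])
    return CompressionCurve(time_ms=centers, normalized_sd=nsd,
                            norm_windows_ms=tuple(norm_windows_ms),
                            t_max_compression_ms=t_min, is_flat=flat)
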