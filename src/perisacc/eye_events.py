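"""Saccade detection and perisaccadic snippet extraction.

Saccades are detected from uniformly sampled gaze traces by a speed
criterion (default 80 deg/s, 2-D speed). Around each isolated saccade a
snippet covering 200 ms before to 450 ms after onset is cut out; snippets
are eligible only if no other saccade onset falls inside that window and
the eye stays within the central part of the screen during the slow
phases. Spike trains are averaged across eligible snippets in 20 ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: perisaccadic isolation window in ms relative to saccade onset
PERI_WINDOW_MS = (-200.0, 450.0)

#: width of analysis bins, ms
BIN_MS = 20.0

#: number of analysis bins; 33 bins of 20 ms tile [-200, 460) ms.  The last
#: bin reaches 10 ms past the isolation bound so that the grid is uniform.
N_BINS = 33


def bin_left_edges(bin_ms: float = BIN_MS, start_ms: float = -200.0,
                   n_bins: int = N_BINS) -> np.ndarray:
    """Left edges of the perisaccadic analysis bins, ms from saccade onset."""
    return start_ms + bin_ms * np.arange(n_bins)


def bin_centers(bin_ms: float = BIN_MS, start_ms: float = -200.0,
                n_bins: int = N_BINS) -> np.ndarray:
    return bin_left_edges(bin_ms, start_ms, n_bins) + bin_ms / 2.0


@dataclass
class EyeTrace:
    """Uniformly sampled 2-D gaze positions.

    time_ms must be uniform and strictly increasing; positions in degrees.
    """

    time_ms: np.ndarray
    horiz_deg: np.ndarray
    vert_deg: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.horiz_deg = np.asarray(self.horiz_deg, dtype=float)
        self.vert_deg = np.asarray(self.vert_deg, dtype=float)
        if not (self.time_ms.shape == self.horiz_deg.shape == self.vert_deg.shape):
            raise ValueError("time and position arrays must have equal shapes")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.time_ms.size >= 2:
            dt = np.diff(self.time_ms)
            expected = 1000.0 / self.sampling_rate_hz
            if np.any(dt <= 0) or not np.allclose(dt, expected, rtol=1e-6, atol=1e-6):
                raise ValueError("eye trace must be uniformly sampled at the "
                                 "stated sampling rate")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def speed_deg_s(self, two_dimensional: bool = True) -> np.ndarray:
        """Instantaneous speed from centered finite differences."""
        t_s = self.time_ms / 1000.0
        vx = np.gradient(self.horiz_deg, t_s)
        if not two_dimensional:
            return np.abs(vx)
        vy = np.gradient(self.vert_deg, t_s)
        return np.hypot(vx, vy)


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_speed_deg_s: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must follow onset")


@dataclass(frozen=True)
class PerisaccadicSnippet:
    """An isolated saccade together with its analysis window and label."""

    saccade: SaccadeEvent
    window_ms: tuple[float, float] = PERI_WINDOW_MS
    isolation_ok: bool = True
    central_ok: bool = True
    heading_deg: float | None = None

    @property
    def eligible(self) -> bool:
        return self.isolation_ok and self.central_ok


def detect_saccades(trace: EyeTrace, speed_threshold_deg_s: float = 80.0,
                    min_duration_ms: float = 6.0,
                    two_dimensional: bool = True) -> list[SaccadeEvent]:
    """Detect saccades by a speed-threshold criterion.

    Onset is the first sample at or above threshold whose predecessor is
    below; offset is the first subsequent sample back below threshold.
    Events shorter than ``min_duration_ms`` are discarded as single-sample
    noise. Events are returned sorted by onset.
    """
    if trace.time_ms.size < 3:
        raise ValueError("trace must contain at least 3 samples")
    if speed_threshold_deg_s <= 0:
        raise ValueError("speed threshold must be positive")
    speed = trace.speed_deg_s(two_dimensional=two_dimensional)
    above = speed >= speed_threshold_deg_s
    # run starts: sample above with previous sample below
    starts = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    events: list[SaccadeEvent] = []
    t = trace.time_ms
    for i0 in starts:
        below = np.flatnonzero(~above[i0:])
        if below.size == 0:
            break  # runs off the end of the trace: no offset sample
        i1 = i0 + int(below[0])  # first sample back below threshold
        if t[i1] - t[i0] < min_duration_ms:
            continue
        amp = float(np.hypot(trace.horiz_deg[i1] - trace.horiz_deg[i0],
                             trace.vert_deg[i1] - trace.vert_deg[i0]))
        events.append(SaccadeEvent(onset_ms=float(t[i0]), offset_ms=float(t[i1]),
                                   amplitude_deg=amp,
                                   peak_speed_deg_s=float(speed[i0:i1].max())))
    return events


def _heading_for(onset_ms: float, schedule) -> float | None:
    if schedule is None:
        return None
    for start, stop, heading in schedule:
        if start <= onset_ms < stop:
            return float(heading)
    return None


def select_snippets(saccades: list[SaccadeEvent], trace: EyeTrace,
                    central_limit_deg: float = 20.0,
                    window_ms: tuple[float, float] = PERI_WINDOW_MS,
                    schedule=None) -> list[PerisaccadicSnippet]:
    """Return eligible perisaccadic snippets.

    A snippet around a saccade is eligible when (i) no other saccade onset
    falls in ``window_ms`` relative to this saccade's onset, and (ii) the
    eye stays inside the central window (a ``central_limit_deg``-wide
    window, i.e. half-width ``central_limit_deg / 2``, on both axes)
    throughout the slow phases of the window. The window must lie fully
    inside the trace. ``schedule`` is an optional list of
    ``(start_ms, stop_ms, heading_deg)`` segments used to label snippets.
    """
    w0, w1 = window_ms
    half = central_limit_deg / 2.0
    onsets = np.array([s.onset_ms for s in saccades])
    t = trace.time_ms
    out: list[PerisaccadicSnippet] = []
    for sac in saccades:
        lo, hi = sac.onset_ms + w0, sac.onset_ms + w1
        if lo < t[0] or hi > t[-1]:
            continue  # window not fully covered by the trace
        others = onsets[(onsets >= lo) & (onsets <= hi) & (onsets != sac.onset_ms)]
        if others.size:
            continue
        # slow phases: the window minus this saccade's own flight time
        in_win = (t >= lo) & (t <= hi)
        slow = in_win & ~((t >= sac.onset_ms) & (t < sac.offset_ms))
        central = bool(np.all(np.abs(trace.horiz_deg[slow]) <= half)
                       and np.all(np.abs(trace.vert_deg[slow]) <= half))
        if not central:
            continue
        out.append(PerisaccadicSnippet(saccade=sac, window_ms=window_ms,
                                       heading_deg=_heading_for(sac.onset_ms,
                                                                schedule)))
    return out


@dataclass
class BinnedResponse:
    """Perisaccadically aligned, snippet-averaged firing rates.

    ``rates`` maps heading (deg) to a length-``n_bins`` array of mean rates
    in spikes/s; ``n_snippets`` records how many snippets entered each
    average.
    """

    bin_left_ms: np.ndarray
    rates: dict[float, np.ndarray]
    n_snippets: dict[float, int]
    bin_ms: float = BIN_MS

    @property
    def bin_center_ms(self) -> np.ndarray:
        return self.bin_left_ms + self.bin_ms / 2.0

    def headings(self) -> list[float]:
        return sorted(self.rates)


def bin_perisaccadic_rates(spike_times_ms: np.ndarray,
                           snippets: list[PerisaccadicSnippet],
                           bin_ms: float = BIN_MS,
                           start_ms: float = -200.0,
                           n_bins: int = N_BINS) -> BinnedResponse:
    """Average a spike train across snippets in perisaccadic bins.

    Snippets without a heading label are ignored. For each heading the
    rate in bin j is the total spike count over snippets in
    ``[onset + edge_j, onset + edge_{j+1})`` divided by
    ``n_snippets * bin width``.
    """
    spikes = np.sort(np.asarray(spike_times_ms, dtype=float))
    edges = start_ms + bin_ms * np.arange(n_bins + 1)
    counts: dict[float, np.ndarray] = {}
    nsnip: dict[float, int] = {}
    for snip in snippets:
        h = snip.heading_deg
        if h is None:
            continue
        c, _ = np.histogram(spikes, bins=snip.saccade.onset_ms + edges)
        counts[h] = counts.get(h, 0) + c
        nsnip[h] = nsnip.get(h, 0) + 1
    rates = {h: counts[h] / (nsnip[h] * bin_ms / 1000.0) for h in counts}
    return BinnedResponse(bin_left_ms=edges[:-1], rates=rates,
                          n_snippets=nsnip, bin_ms=bin_ms)


def window_mask(bin_left_ms: np.ndarray, start_ms: float,
                stop_ms: float) -> np.ndarray:
    """Bins whose left edge lies in ``[start_ms, stop_ms)``."""
    return (bin_left_ms >= start_ms) & (bin_left_ms < stop_ms)
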