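"""Multiplicative perisaccadic gain kernels.

A kernel is a unitless gain profile over time relative to saccade onset.
Gain 1 means no modulation; values below 1 suppress, above 1 enhance.
Kernels are normalized so that their mean gain over the flanks (more than
100 ms before or after saccade onset) equals 1, which anchors "no
modulation" far from the saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: flank boundary in ms: |t| >= FLANK_MS counts as "far from the saccade"
FLANK_MS = 100.0

#: default time axis, ms relative to saccade onset, 1 ms resolution
DEFAULT_TIME_MS = np.arange(-200.0, 461.0, 1.0)


@dataclass(frozen=True)
class SuppressionKernel:
    """Time-resolved multiplicative gain around a saccade.

    Parameters
    ----------
    time_ms : array
        Strictly increasing times in ms relative to saccade onset.
    gain : array
        Unitless gain at each time point.
    label : str
        One of ``"global"``, ``"congruent"``, ``"incongruent"`` or
        ``"identity"`` (free-form labels are allowed).
    """

    time_ms: np.ndarray
    gain: np.ndarray
    label: str = "global"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        g = np.asarray(self.gain, dtype=float)
        if t.ndim != 1 or t.shape != g.shape:
            raise ValueError("time_ms and gain must be 1-D arrays of equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_ms must be strictly increasing with >= 2 samples")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "gain", g)

    def flank_mask(self) -> np.ndarray:
        return (self.time_ms < -FLANK_MS) | (self.time_ms >= FLANK_MS)

    def flank_mean(self) -> float:
        mask = self.flank_mask()
        if not mask.any():
            raise ValueError("kernel time axis has no flank samples beyond +/-100 ms")
        return float(self.gain[mask].mean())

    def normalized(self) -> "SuppressionKernel":
        """Rescale so the flank-mean gain is exactly 1."""
        m = self.flank_mean()
        if m <= 0:
            raise ValueError("flank mean gain must be positive to normalize")
        return replace(self, gain=self.gain / m)

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self.flank_mean() - 1.0) <= tol

    def __call__(self, t) -> np.ndarray:
        """Gain at arbitrary times (linear interpolation, 1 outside the axis)."""
        return np.interp(np.asarray(t, dtype=float), self.time_ms, self.gain,
                         left=1.0, right=1.0)


def identity_kernel(time_ms: np.ndarray | None = None,
                    label: str = "identity") -> SuppressionKernel:
    """Gain identically 1: no perisaccadic modulation."""
    t = DEFAULT_TIME_MS if time_ms is None else np.asarray(time_ms, dtype=float)
    return SuppressionKernel(t, np.ones_like(t), label=label)


def gaussian_gain_kernel(depth: float, center_ms: float, width_ms: float,
                         label: str, time_ms: np.ndarray | None = None,
                         ) -> SuppressionKernel:
    """Gaussian gain deviation ``1 + depth * exp(-(t-center)^2 / 2 width^2)``.

    Negative ``depth`` gives a suppression dip, positive an enhancement
    bump. The result is flank-normalized.
    """
    t = DEFAULT_TIME_MS if time_ms is None else np.asarray(time_ms, dtype=float)
    g = 1.0 + depth * np.exp(-0.5 * ((t - center_ms) / width_ms) ** 2)
    return SuppressionKernel(t, g, label=label).normalized()


def average_kernels(kernels, weights=None, label: str = "global") -> SuppressionKernel:
    """Weighted average of kernels on the first kernel's time axis, re-normalized."""
    kernels = list(kernels)
    if not kernels:
        raise ValueError("need at least one kernel to average")
    t = kernels[0].time_ms
    w = np.ones(len(kernels)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    g = sum(wi * k(t) for wi, k in zip(w, kernels))
    return SuppressionKernel(t, g, label=label).normalized()


def default_kernels(suppression_depth: float = 0.5,
                    suppression_center_ms: float = 80.0,
                    enhancement_depth: float = 0.5,
                    enhancement_center_ms: float = 120.0,
                    width_ms: float = 40.0) -> dict[str, SuppressionKernel]:
    """Empirically shaped default kernel set.

    Congruent suppression peaks 80 ms after saccade onset; the mirrored
    incongruent enhancement (release from inhibition) peaks 40 ms later at
    120 ms. The global kernel is the population average of the two
    condition profiles, as an all-neuron mean modulation would be.
    """
    cong = gaussian_gain_kernel(-suppression_depth, suppression_center_ms,
                                width_ms, "congruent")
    incong = gaussian_gain_kernel(+enhancement_depth, enhancement_center_ms,
                                  width_ms, "incongruent")
    glob = average_kernels([cong, incong], label="global")
    return {"congruent": cong, "incongruent": incong, "global": glob,
            "identity": identity_kernel()}
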