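# Methods

This note documents the models, conventions, and numerical choices behind
`perisacc`, and what the synthetic generators do and do not emulate.

## Bin grid and time conventions

All perisaccadic analyses live on a 20 ms bin grid aligned to saccade
onset. The isolation window for snippets is [−200, +450] ms; 650 ms is
not a multiple of 20 ms, so the grid uses 33 bins with left edges
−200, −180, …, +440 ms — the last bin reaches 10 ms past the isolation
bound so the tiling is uniform. Window selections (fit window 300–450 ms,
index window 40–160 ms, normalization windows) pick bins by left edge;
reported event times (e.g. the time of maximum compression) are bin
centers, and peak times of modulation time courses are conventionally
read from the two-bin running mean, whose timestamps fall on even 20 ms
multiples. Headings are in degrees of azimuth, rightward positive; all
times are ms relative to saccade onset.

## Saccade detection

Speed is the Euclidean norm of the centered-finite-difference velocity of
the horizontal and vertical traces (a 1-D option exists). Onset is the
first sample at or above the 80°/s criterion whose predecessor is below;
offset is the first subsequent sample below. Events shorter than 6 ms
(3 samples at 500 Hz) are discarded as single-sample noise. The
"central 20°" position criterion is read as a 20°-wide window (±10° on
both axes) and is configurable, since a ±20° reading is also defensible.
The isolation rule is asymmetric by construction: a snippet is dropped
when *another* onset falls in [−200, +450] ms around *this* saccade, so
of two saccades 300 ms apart only the earlier one is excluded.

## Tuning and decoding

Tuning significance uses the Kruskal–Wallis statistic (chi-square
approximation, k−1 df, midrank ties) on firing rates in 1000 ms trial
slices; slices overlapping saccades can optionally be excluded (the
default keeps them). The tuning line y = a·x + b is an ordinary
least-squares fit through the three (heading, mean 300–450 ms rate)
points. Decoding inverts the line per neuron, x = (y − b)/a; neurons with
|a| < 10⁻⁶ (spikes/s)/deg are excluded because the inverse blows up, and
the significance filter makes such cells rare. The population readout is
the per-bin median (midpoint of the central order statistics for even
counts); a neuron missing a bin is dropped from that bin's median only.
Per-bin separation of the decoded headings is tested with Kruskal–Wallis
on the per-neuron decoded values and Benjamini–Hochberg FDR across the
33 bins. Decoded values are deliberately not clipped to the stimulus
range, so centrifugal biases remain visible.

## The compression statistic

Compression is the SD (ddof = 1) across the heading time courses of the
raw (un-smoothed) decoded values, divided by its mean over two 100 ms
windows chosen to be free of saccadic influence: −200…−100 ms and
200…300 ms. By construction the normalized curve averages 1 over those
windows; its argmin is the time of maximum compression. A curve whose
range is below 10⁻⁹ (neural) — or whose dip is shallower than a
configurable 0.1 (behavioral) — is reported as flat with no meaningful
minimum. A zero normalization mean signals degenerate input (identical
series) and is rejected rather than normalized.

## Modulation and kernels

Response modulation is the binned rate minus its full-window mean.
Population time courses carry percentile-bootstrap CIs (default 1000
resamples) with the **neuron** as the resampling unit; BCa intervals were
not used, a deliberate simplification documented here because percentile
and BCa intervals can differ for skewed per-neuron distributions. Each
neuron contributes its preferred-heading response to the congruent set
and its anti-preferred response to the incongruent set, so both sets
always have the full population's cardinality. Condition medians of the
modulation index are tested with one-sided sign tests against 1
(congruent below, incongruent above). Gain kernels are condition time
courses in raw rate units divided by their flank mean (bins with left
edge < −100 ms or ≥ +100 ms), making "no modulation far from the
saccade" exactly 1.

## The virtual-population model

The model population has 71 neurons (38 negative, 33 positive slopes).
Slope magnitudes are log-normal with median 0.2 (spikes/s)/deg
(log-SD 0.5) and intercepts log-normal with median 10 spikes/s
(log-SD 0.4): a tuning span of ~12 spikes/s over ±30° on a ~10 spikes/s
baseline, typical of heading-tuned MST/VIP cells. The intercept-to-slope
ratio matters: a multiplicative gain g moves a neuron's decoded estimate
to g·x + (g − 1)·b/a, so b/|a| sets how far suppression drags estimates
toward (or past) the center. With the default population, the default
kernel depths produce center-directed shifts without sign reversals.

Perisaccadic modulation is a pointwise multiplicative gain aligned to
saccade onset (not a sliding convolution — a near-1 sliding kernel cannot
produce a localized dip). The default kernel set is Gaussian-shaped:
congruent suppression of depth 0.5 peaking 80 ms after onset (SD 40 ms),
a mirrored incongruent enhancement peaking 40 ms later at 120 ms, and a
global kernel equal to the normalized average of the two, as an
all-neuron mean modulation would be. In selective mode,
stimulus-preferring neurons receive the congruent kernel and the others
the incongruent kernel; for the 0° stimulus neither subpopulation is
preferred and every neuron receives the congruent kernel at half depth
(a configurable choice — interpolation by preference match would be an
alternative). Gaussian rate noise (SD 2 spikes/s per bin) is added, rates
are clamped at 0 (a zero rate decodes to the saturation value −b/a),
each of the 50 repetitions is decoded, the decoded time courses are
averaged across repetitions, and compression is computed from the
averaged curves. With these conditions the selective-mode minimum falls
at the 80–100 ms bin (reported center 90 ms, occasionally 70 ms under
Monte-Carlo jitter) at a depth of ~0.25, while the global mode stays
above 0.8 — the qualitative contrast is large and stable.

## Synthetic generators: what they emulate and what they don't

*Eye traces* alternate constant-velocity slow phases (8°/s) with
minimum-jerk resetting saccades (mean amplitude 8°, peak speed 300°/s,
duration set so the analytic peak speed is exact), onset-to-onset
intervals shifted-exponential with mean 1000 ms (minimum 250 ms), at
500 Hz. Saccade amplitudes partially correct the accumulated drift
(gain 0.5), keeping the beating field on screen; occasional long slow
phases still leave the central ±10° zone and are then removed by the
central-position filter, as in real recordings. The generator provides
ground-truth onsets and the analytic 80°/s crossing time of each
minimum-jerk profile for detector validation. It does not model
main-sequence relationships, vergence, torsion, blinks, or tracker
noise (positional noise is available but defaults to 0).

*Spike trains* are inhomogeneous Poisson with rate
max(0, gain(t)·(a·x + b) + noise) on a 1 ms grid; optional Gaussian rate
noise is piecewise constant over 20 ms blocks. Real MST/VIP spike trains
have refractoriness, bursting, and correlated variability that Poisson
generation ignores — passing tests therefore validate the analysis
chain, not those biological features.

*Behavioral trials* report
gaze + (1 − c(t))·(heading-in-gaze-coordinates + bias) + noise, with c(t)
a Gaussian compression profile (default peak 0.8, SD 50 ms, centered at
saccade onset; the pipeline default centers it at −5 ms to emulate the
observed pre-saccadic peak), report noise SD 3°, ~200 saccade trials per
heading with onsets uniform over ±200 ms, and a central bias expressed
as the inward displacement (deg) of the most eccentric heading. The gaze
offset α shifts the compression center; a head offset does not. Ruler
quantization, per-subject saccade-latency correction, and lapses are not
modeled.

## Psychophysical analyses

Perceived-heading series use a centered 5-point running mean with
truncated edge windows; behavioral compression interpolates the smoothed
series onto a common ~2.5 ms grid and normalizes by the SD at
|t| ≥ 100 ms (the "up to 100 ms before and after" phrasing is ambiguous;
this symmetric reading is configurable). The cross-correlation latency
resamples both curves to a 20 ms grid, scans integer-bin lags over
±300 ms, and reports the lag with the highest Pearson correlation over
the overlap (≥5 points); positive τ means the neural curve lags the
behavioral one. d′ divides the difference of the two window means by the
(n−1)-weighted pooled SD; per-subject percent correct are the samples.
The reference-frame analysis reads the across-heading mean percept at
the time of maximum compression and classifies it against the variant
predictions (head offset, 0, 0, gaze offset) by summed absolute error
across conditions; when all predictions agree within 2° the variants are
reported as indistinguishable.

## Problem sizes and determinism

Default sizes — 71 neurons, 3 physiology headings with 60–120 s of
simulated tracking each (30–60 eligible snippets per heading), 50 model
repetitions, 200 behavioral trials per heading, 1000 bootstrap
resamples — were chosen so a full pipeline run completes in seconds while
keeping Monte-Carlo error well below the effects of interest. Every
generator and resampling routine takes an explicit seed (or an inherited
`numpy` Generator); the pipeline spawns per-stage seeds from the run seed
so that a fixed configuration reproduces every output byte-identically.

## Known limitations

The accession tier of the analysis (applying the pipeline to the
deposited monkey/human recordings) needs those data on disk under
`data/zenodo-837063/`; without them the corresponding check fails by
design. The modulation-index late window (300–450 ms) covers the last
bin's 440–460 ms extension. The sign convention of τ, and the center/left
-edge labeling above, should be kept in mind when comparing timing values
with other toolchains.
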