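# Methods

This note records the model, the numerical choices, and what the synthetic
data generator does and does not establish.

## Spectral decomposition

The time-frequency transform is a complex Morlet wavelet evaluated at 0.5-s
step centers on a log-spaced grid of `n_bins = 100` frequencies from
`f_min = 0.1` to `f_max = 150` Hz.  The cycle count is linear in *bin index*
from 3 to 30, which pins the effective analysis window to 30 s at 0.1 Hz and
0.2 s at 150 Hz.  One hundred bins give ≈31 bins per decade — enough to
separate the <1 Hz slow-oscillation band from the 1–3 Hz delta band, which
is the whole point of the display.

Open conventions were fixed as follows:

* **Kernel support and envelope.** The kernel is truncated to exactly
  `cycles/f` seconds; the Gaussian envelope SD is support/7, so the envelope
  has decayed to ≈e⁻⁶ at the truncation edges and the truncation artifact is
  negligible.
* **Normalisation.** Kernels are L1-normalised on the envelope.  Absolute
  scale is irrelevant: every downstream consumer sees dB *relative to the
  whole-night mean*, and any linear normalisation cancels there.  The
  amplitude-doubling property (+20·log10 2 ≈ 6.02 dB) holds regardless.
* **Evaluation.** Coefficients are computed by per-frequency overlap-add FFT
  convolution of the full signal with the kernel, then sampled at the step
  centers.  This is algebraically the same windowed inner product evaluated
  directly, at a small fraction of the cost for whole-night inputs.
* **Edges.** Steps whose window overruns the recording are computed on the
  zero-padded signal and flagged per (step, frequency) in `edge_flags`;
  edge-flagged values are excluded from the baseline mean.  At 0.1 Hz the
  first and last 15 s of the night are always edge-flagged.
* **Power floor.** Power is floored at 1e-12 before the log, so silence maps
  to exactly −120 dB instead of −∞.

## Artifact rule

Movement artifacts are tagged per 30-s window by `s_w = max|x_w − mean(x_w)|`.
Window *w* is flagged iff `s_w > mean(s_{−w}) + 5·SD(s_{−w})`, where `s_{−w}`
are the statistics of all *other* windows (leave-one-out, sample SD, strict
inequality).  The leave-one-out form follows from the rule's phrasing
("exceeds … all other windows"); it also makes the threshold robust to the
outlier itself inflating the SD.  With fewer than three complete windows the
SD of "the others" is undefined and the operation refuses to run.  Flagged
windows are never deleted — they are excluded only from the baseline mean.

## Baseline and display transforms

The baseline is the per-frequency mean dB over steps that are neither in a
flagged artifact window nor edge-flagged at that frequency; if every window
is flagged the baseline falls back to all steps with a warning.  Subtracting
it leaves per-frequency means of exactly zero over the steps that defined it.

Line-noise masking (default 50–70 Hz) replaces each in-band bin by the mean
of the two bins immediately below and the two immediately above the band,
and the 40-s moving average (centered, truncated at the edges) smooths the
display.  Both are display-only: band features and the dominant-frequency
dots are contractually computed from the *baselined, unsmoothed, unmasked*
spectrogram, and the objects carry a `stage_tag` so wiring mistakes raise
instead of silently degrading the staging.  Dominant-frequency ties break
toward the lower frequency (deterministic, and favouring the
physiologically salient slow bands).

## Staging model

Each 30-s epoch yields `y ∈ ℝ⁵`: mean relative dB in Lo Deep [0.1, 1), Hi
Deep [1, 3), Light [10.5, 16), REM [16, 30) and Wake [37, 47) Hz
(half-open, lower-inclusive intervals; the trailing partial epoch is
dropped).  The Wake band sits below the 50–70 Hz mask band by construction.

The HMM has five hidden states with transition matrix `Q` initialised to
0.95 on the diagonal and 0.0125 off it.  Choices the initialisation leaves
open were resolved as:

* **Initial distribution** `π`: uniform (0.2 each) — no reason to bias the
  first epoch.
* **Emission means**: state *j* is seeded from the epochs whose strongest
  band is band *j*.  This ties each state to its intended stage from the
  start, so the decoded state sequence maps to stage labels with no
  post-hoc relabelling, and the identity is frozen through EM.  If a band
  claims no epochs, its state falls back to the global mean plus a 1-dB
  offset in its own column.
* **Covariances**: full 5×5 matrices, initialised to the global feature
  covariance.  Every M-step re-adds a diagonal ridge of `1e-6·trace(Σ)/5`
  so degenerate inputs (e.g. identical feature rows) keep Σ positive
  definite.

EM is the standard scaled Baum–Welch forward–backward with per-step
emission-shift stabilisation (the per-row max of the log-density is factored
out before exponentiation, so far-from-model epochs cannot underflow the
scaled recursion).  Iteration stops when the relative log-likelihood change
drops below 1e-6 or after 100 iterations.  The likelihood trace is monotone
non-decreasing; because the ridge is re-applied after each exact M-step, a
wobble smaller than the convergence tolerance can occur at the optimum and
is treated as termination, while any larger decrease raises an error as an
EM-contract violation.  Decoding is log-space Viterbi with ties broken
toward the lower state index.  Fitting is per night; no pooling across
recordings.

**Sleep metrics.** Sleep onset is the start of the first run of ≥5
consecutive non-Wake epochs (2.5 min; configurable).  Total sleep time
counts post-onset non-Wake epochs; stage hours and percentages cover all
post-onset epochs including Wake, so the percentages sum to 100.

## EDA statistics

EDA samples map to epochs by left-edge containment in `[onset, onset+30)`.
The four statistics: per-stage means with stage-vs-rest ratios gated at
0.25 μS (below the gate a ratio of means can look large with no real peak,
so ratios are suppressed); the quarter (1–4, equal duration, post-onset) of
maximal mean EDA, ties to the earliest; first-vs-last-minute deltas over
stage bouts lasting ≥8 min with at most two isolated single-*epoch*
excursions tolerated (the hypnogram is the stage clock, so "sample
excursions" are read as 30-s epochs; bouts must start and end on the target
stage); and the rising-time fraction, the percentage of first differences
exceeding 0.0001 μS per sample interval, attributed to the stage of the
left sample.  The derivative threshold is rate-dependent (at 4 Hz it equals
4e-4 μS/s) and is exposed in the configuration.  Absent stages yield `None`
rather than errors.

## Synthetic nights

The generator emulates the macrostructure the pipeline must resolve: 15 min
of Wake, then ~90-min cycles of Light → Deep → Light → REM (30/35/10/25% of
the cycle, jittered ±10% by seed, snapped to 30-s epochs), with Deep = Hi
Deep in the first half of the cycles and Lo Deep thereafter.  EEG is a
unit-RMS 1/f background plus stage-locked oscillations: a drifting 0.4–0.9 Hz
sinusoid (amplitude 6, the largest, mirroring high-amplitude slow waves),
1.5–2.5 Hz at amplitude 4, 12–14 Hz spindle bursts of 0.7 s every 4–8 s at
amplitude 3, and 16–30 / 37–47 Hz band-noise boosts at amplitude 1.5 for
REM and Wake.  The default rate is 250 Hz — comfortably above Nyquist for
the 47-Hz band while keeping whole-night runs fast; rates up to 540 Hz are
supported.

EDA sits at 0.3 μS with a ±0.02 μS night-scale drift, ramps +0.6 μS linearly
across every Lo Deep segment, and decays exponentially (τ = 5 min)
afterwards.  Noise (SD 0.01 μS) is temporally smoothed with a 10-s Gaussian
kernel: tonic skin conductance varies over seconds, and white per-sample
noise would make the derivative-sign statistic meaningless in a way real
recordings are not.

Artifact injection adds a square pulse over the *middle half* of a 30-s
window — movement artifacts are brief, and a pulse spanning an entire window
would be invisible to a statistic that subtracts the within-window mean.

**What passing on synthetic nights shows.** The generator produces cleanly
band-separated, stationary-within-stage signals with instantaneous
transitions.  Perfect or near-perfect staging accuracy on it demonstrates
that the spectral features, EM fitting and decoding are wired and
implemented correctly — not that real nights, with gradual transitions,
mixed-frequency epochs, movement-rich Wake and inter-subject variability,
would score at that accuracy.  There are no K-complexes, no spindle chirps,
no EMG contamination, and only a single channel; the FF difference-channel
path is exercised with constructed multichannel inputs instead.

## Problem sizes

The default acceptance run uses a four-cycle (~6.3 h) night at 250 Hz for
the end-to-end measurements, a 100-bin grid, 100 random T=8 instances for
the Viterbi-vs-enumeration check (5⁸ = 390 625 paths each), 25 T=6
instances for the forward-likelihood check, and 2 000 epochs for EM
parameter recovery.  The test suite uses a ~2-h two-deep-segment night for
the same end-to-end property so the default run stays fast.

## Known limitations

* EDF reading is delegated to `mne`; only the features EDF itself carries
  (per-channel rates, labels) are surfaced.  Unequal channel rates are
  upsampled by linear interpolation to the maximum rate, which preserves
  the low-frequency content the analysis cares about but adds no
  information above the original Nyquist of the slower channels.
* Device clocks are assumed to share t=0 ("approximately synchronized"
  start); alignment truncates to the overlap and performs no
  cross-correlation resynchronisation.
* The EDA sampling rate is not discoverable from a bare CSV and must be
  supplied (default 4 Hz, the common wristband rate).
* Per-night analysis only: cohort-level aggregation (group means, ANOVA)
  is out of scope, though per-bout values are returned for downstream use.
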