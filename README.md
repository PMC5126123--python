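# somnigram

Whole-night sleep-EEG analysis from a single forehead channel: a
Morlet-wavelet spectral report, unsupervised five-stage HMM sleep scoring,
and per-stage electrodermal-activity (EDA) statistics — plus a
ground-truthed synthetic-night generator so the entire pipeline can be
exercised without any recorded data.

## The problem

Conventional sleep scoring collapses all slow-wave sleep below 3 Hz into one
"deep" stage.  When the spectrum is computed down to 0.1 Hz on a
log-frequency axis, slow-wave sleep splits into two visually and
physiologically distinct states: **Lo Deep** (dominant power 0.1–1 Hz, the
cortical slow oscillation) and **Hi Deep** (dominant power 1–3 Hz, delta).
Skin conductance measured at the wrist rises almost exclusively during Lo
Deep bouts, rarely during Hi Deep — evidence that the two are different
states.  This package implements the full analysis that exposes the split
and quantifies the EDA association, for researchers working with
inexpensive 2-channel home EEG devices and EDA wristbands.

## The method

1. **Spectral decomposition.** Complex Morlet wavelets on a log-spaced grid
   of 100 frequencies from 0.1 to 150 Hz, every 0.5 s.  The cycle count
   grows linearly over bin index from 3 to 30, so the analysis window
   shrinks from 30 s at 0.1 Hz to 0.2 s at 150 Hz.  Power is
   `P(t,f) = W·W*`, reported as `10·log10 P` dB.
2. **Artifact tagging.** Per 30-s window, the statistic `max|x − x̄|`;
   windows exceeding the mean + 5 SD of all *other* windows are tagged
   (never deleted — they are only excluded from the baseline).
3. **Baselining.** The per-frequency whole-night mean dB over artifact-free
   time is subtracted, giving *relative* power.  Line noise (50–70 Hz,
   optionally 110–130 Hz) is masked for display only; a 40-s moving average
   smooths the display spectrogram only.
4. **Staging.** Each 30-s epoch becomes an observation vector
   `y ∈ ℝ⁵` of mean relative dB in five bands (Lo Deep 0.1–1, Hi Deep 1–3,
   Light 10.5–16, REM 16–30, Wake 37–47 Hz).  Stages follow a hidden Markov
   model with 5×5 transition matrix `Q` (initialised sticky: 0.95 diagonal,
   0.0125 off-diagonal) and Gaussian emissions `R(y|j) = N(μ_j, Σ_j)`.  All
   parameters are fitted per night by Baum–Welch EM; the hypnogram is the
   Viterbi maximum-a-posteriori state path.
5. **EDA quantification.** Against the hypnogram: per-stage means and
   stage-vs-rest ratios (gated at 0.25 μS), the quarter of the post-onset
   night with the highest mean EDA, first-vs-last-minute deltas over
   sustained (≥8 min) stage bouts, and the percentage of time EDA is rising
   (first difference > 0.0001 μS/sample).

## Worked example

Simulate a two-cycle night and score it:

```sh
$ somnigram simulate --out night --n-cycles 2 --seed 1
wrote night: eeg.csv eda.csv hypnogram_truth.csv params.json (3.39 h night)

$ somnigram stage --eeg night/eeg.csv --out staged --truth night/hypnogram_truth.csv
staged 407 epochs; EM iterations: 4; accuracy vs truth: 100.0%
```

`staged/metrics.json` then holds the per-night summary (abridged):

```json
{
  "hours": {"HiDeep": 0.525, "Light": 1.258, "LoDeep": 0.575, "REM": 0.783, "Wake": 0.0},
  "pct":   {"HiDeep": 16.7,  "Light": 40.1,  "LoDeep": 18.3,  "REM": 24.9,  "Wake": 0.0},
  "sleep_onset_latency_min": 15.0,
  "total_sleep_time_h": 3.142
}
```

The simulated night begins with 15 min of Wake, so the detected sleep-onset
latency is 15 min; the first (Hi Deep) and second (Lo Deep) cycles give
roughly equal deep-sleep shares, and every epoch matches the generator's
ground truth.  `somnigram report` additionally renders the full sleep
report (spectrogram heat map, dominant-frequency dots, EDA trace,
hypnogram), and `somnigram eda` writes the four per-stage EDA statistics.

## Layout

| Path | Contents |
| --- | --- |
| `src/somnigram/io_formats.py` | EDF/CSV readers, FF difference channel, alignment, hypnogram I/O |
| `src/somnigram/spectral.py` | wavelet spectrogram, artifact tagging, baseline, line mask, smoothing |
| `src/somnigram/staging.py` | band features, HMM init / EM / Viterbi, sleep metrics |
| `src/somnigram/eda_metrics.py` | the four per-stage EDA statistics |
| `src/somnigram/report_viz.py` | the stacked whole-night report figure |
| `src/somnigram/synthetic.py` | ground-truthed night generator and corruption injectors |
| `src/somnigram/cli.py` | `somnigram report / stage / eda / simulate` |
| `docs/methods.md` | modelling choices, parameters, limitations |
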