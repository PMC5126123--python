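"""Ground-truthed synthetic whole-night EEG + EDA generation.

The generator emulates the macrostructure a single-channel forehead recording
shows over a night: an initial Wake period, then ~90-min cycles of
Light → Deep → Light → REM, with deep sleep expressed as Hi Deep (dominant
1–3 Hz) in the early cycles and Lo Deep (dominant <1 Hz) in the later ones.
Each stage contributes a characteristic oscillation added onto a shared 1/f
background: a large slow oscillation drifting 0.4–0.9 Hz for Lo Deep, a
1.5–2.5 Hz delta oscillation for Hi Deep, 12–14 Hz spindle bursts (0.7 s
every 4–8 s) for Light, a broadband 16–30 Hz boost for REM, and a 37–47 Hz
boost for Wake.  EDA sits near 0.3 μS and ramps up within every Lo Deep
segment, peaking at segment end and decaying exponentially afterwards — the
behaviour the per-stage EDA statistics are designed to detect.

Everything is deterministic given (parameters, seed).  The point is relative
band dominance per stage, not biophysical realism: there are no K-complexes,
no spindle chirps, and stage transitions are instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigError
from .io_formats import EDASeries, Hypnogram, Recording

DEFAULT_RATE = 250.0  # Hz; covers the 47-Hz Wake band with margin


@dataclass
class StageSchedule:
    """Ordered (stage, duration_s) segments making up a night."""

    segments: list[tuple[str, float]]
    seed: int = 0

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    def to_hypnogram(self, epoch_s: float = 30.0) -> Hypnogram:
        """Ground-truth hypnogram (segment durations are epoch multiples)."""
        stages: list[str] = []
        for stage, dur in self.segments:
            stages.extend([stage] * int(round(dur / epoch_s)))
        return Hypnogram(stages=stages, epoch_s=epoch_s)

    def segment_bounds(self) -> list[tuple[str, float, float]]:
        out = []
        t = 0.0
        for stage, dur in self.segments:
            out.append((stage, t, t + dur))
            t += dur
        return out


@dataclass
class SynthesisParams:
    """Amplitudes, rates and EDA dynamics for the synthetic night.

    Oscillation amplitudes are in units of the background RMS (the 1/f
    background is normalised to unit standard deviation); the slow
    oscillation is deliberately the largest, mirroring the dominance of
    high-amplitude slow waves in real deep sleep.
    """

    rate: float = DEFAULT_RATE
    background_exponent: float = 1.0
    background_amplitude: float = 1.0
    lo_deep_band: tuple[float, float] = (0.4, 0.9)
    lo_deep_amplitude: float = 6.0
    hi_deep_band: tuple[float, float] = (1.5, 2.5)
    hi_deep_amplitude: float = 4.0
    spindle_band: tuple[float, float] = (12.0, 14.0)
    spindle_amplitude: float = 3.0
    spindle_duration_s: float = 0.7
    spindle_interval_s: tuple[float, float] = (4.0, 8.0)
    rem_band: tuple[float, float] = (16.0, 30.0)
    rem_amplitude: float = 1.5
    wake_band: tuple[float, float] = (37.0, 47.0)
    wake_amplitude: float = 1.5
    wake_min: float = 15.0  # initial Wake segment, minutes
    cycle_min: float = 90.0
    cycle_jitter: float = 0.1  # fractional jitter on cycle length
    eda_rate: float = 4.0
    eda_baseline_uS: float = 0.3
    eda_drift_uS: float = 0.02
    eda_ramp_uS: float = 0.6
    eda_decay_tau_s: float = 300.0
    eda_noise_uS: float = 0.01
    eda_noise_smooth_s: float = 10.0  # tonic EDA varies slowly; noise is low-pass
    channel_label: str = "FF"


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def generate_stage_schedule(
    n_cycles: int = 4,
    seed: int = 0,
    params: SynthesisParams | None = None,
    epoch_s: float = 30.0,
) -> StageSchedule:
    """Initial Wake then ``n_cycles`` of Light→Deep→Light→REM.

    Deep sleep is Hi Deep in the first ``ceil(n/2)`` cycles, Lo Deep after —
    the within-night progression the whole-night display makes visible.
    Cycle lengths are jittered by the seed; all durations round to whole
    30-s epochs so the ground truth aligns with the scoring grid.
    """
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    params = params or SynthesisParams()
    rng = np.random.default_rng(seed)
    n_hi = int(np.ceil(n_cycles / 2))

    def snap(seconds: float) -> float:
        return max(epoch_s, round(seconds / epoch_s) * epoch_s)

    segments: list[tuple[str, float]] = [("Wake", snap(params.wake_min * 60.0))]
    fractions = (("Light", 0.30), ("Deep", 0.35), ("Light", 0.10), ("REM", 0.25))
    for c in range(n_cycles):
        cycle_s = params.cycle_min * 60.0 * (
            1.0 + params.cycle_jitter * rng.uniform(-1.0, 1.0)
        )
        deep = "HiDeep" if c < n_hi else "LoDeep"
        for name, frac in fractions:
            stage = deep if name == "Deep" else name
            segments.append((stage, snap(cycle_s * frac)))
    return StageSchedule(segments=segments, seed=seed)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _background_1_over_f(n: int, rate: float, exponent: float, rng) -> np.ndarray:
    """Unit-RMS noise with power spectral density ∝ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _band_noise(n: int, rate: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _drifting_sine(n: int, rate: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS sinusoid whose instantaneous frequency drifts within band."""
    lo, hi = band
    # slow sinusoidal sweep across the band with a random phase
    sweep_period_s = 60.0
    t = np.arange(n) / rate
    center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    f_inst = center + half * np.sin(2 * np.pi * t / sweep_period_s + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f_inst) / rate
    return np.sqrt(2.0) * np.sin(phase + rng.uniform(0, 2 * np.pi))


def synthesize_eeg(schedule: StageSchedule, params: SynthesisParams | None = None) -> Recording:
    """Stage-specific oscillations added onto a shared 1/f background."""
    params = params or SynthesisParams()
    highest = max(params.wake_band[1], params.rem_band[1])
    if params.rate < 2.0 * highest:
        raise ConfigError(
            f"rate {params.rate:g} Hz is below Nyquist for the {highest:g}-Hz band"
        )
    rng = np.random.default_rng(schedule.seed + 1)
    n = int(round(schedule.total_s * params.rate))
    x = params.background_amplitude * _background_1_over_f(
        n, params.rate, params.background_exponent, rng
    )
    for stage, t0, t1 in schedule.segment_bounds():
        i0, i1 = int(round(t0 * params.rate)), int(round(t1 * params.rate))
        m = i1 - i0
        if m <= 0:
            continue
        if stage == "LoDeep":
            x[i0:i1] += params.lo_deep_amplitude * _drifting_sine(
                m, params.rate, params.lo_deep_band, rng
            )
        elif stage == "HiDeep":
            x[i0:i1] += params.hi_deep_amplitude * _drifting_sine(
                m, params.rate, params.hi_deep_band, rng
            )
        elif stage == "Light":
            x[i0:i1] += _spindle_train(m, params, rng)
        elif stage == "REM":
            x[i0:i1] += params.rem_amplitude * _band_noise(m, params.rate, params.rem_band, rng)
        elif stage == "Wake":
            x[i0:i1] += params.wake_amplitude * _band_noise(m, params.rate, params.wake_band, rng)
    return Recording(
        samples=x[:, None], rate=params.rate, channel_labels=[params.channel_label]
    )


def _spindle_train(m: int, params: SynthesisParams, rng) -> np.ndarray:
    """12–14 Hz bursts of ~0.7 s every 4–8 s under a Hann envelope."""
    rate = params.rate
    out = np.zeros(m)
    burst_len = int(round(params.spindle_duration_s * rate))
    t = 0.0
    lo, hi = params.spindle_interval_s
    while True:
        t += rng.uniform(lo, hi)
        i0 = int(round(t * rate))
        if i0 + burst_len >= m:
            break
        freq = rng.uniform(*params.spindle_band)
        tt = np.arange(burst_len) / rate
        env = np.hanning(burst_len)
        out[i0 : i0 + burst_len] += (
            params.spindle_amplitude
            * np.sqrt(2.0)
            * env
            * np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
        )
    return out


# ---------------------------------------------------------------------------
# EDA synthesis
# ---------------------------------------------------------------------------

def synthesize_eda(schedule: StageSchedule, params: SynthesisParams | None = None) -> EDASeries:
    """Baseline skin conductance with a monotone ramp in every Lo Deep segment.

    The ramp rises linearly over each Lo Deep segment (default +0.6 μS),
    peaks at segment end, then decays exponentially (τ = 5 min); a slow
    sinusoidal drift and temporally smoothed noise sit on top (tonic skin
    conductance varies over seconds, not per sample).  With noise and drift
    disabled the series is strictly rising throughout Lo Deep and non-rising
    elsewhere.
    """
    params = params or SynthesisParams()
    rng = np.random.default_rng(schedule.seed + 2)
    n = int(round(schedule.total_s * params.eda_rate))
    t = np.arange(n) / params.eda_rate
    drift = params.eda_drift_uS * np.sin(
        2 * np.pi * t / schedule.total_s + rng.uniform(0, 2 * np.pi)
    )
    values = params.eda_baseline_uS + drift
    for stage, t0, t1 in schedule.segment_bounds():
        if stage != "LoDeep":
            continue
        in_seg = (t >= t0) & (t < t1)
        values[in_seg] += params.eda_ramp_uS * (t[in_seg] - t0) / (t1 - t0)
        after = t >= t1
        values[after] += params.eda_ramp_uS * np.exp(
            -(t[after] - t1) / params.eda_decay_tau_s
        )
    if params.eda_noise_uS > 0:
        from scipy.ndimage import gaussian_filter1d

        noise = rng.standard_normal(n)
        sigma = params.eda_noise_smooth_s * params.eda_rate
        if sigma > 0:
            noise = gaussian_filter1d(noise, sigma)
            noise /= noise.std()
        values = values + params.eda_noise_uS * noise
    return EDASeries(values=np.clip(values, 0.0, None), rate=params.eda_rate)


# ---------------------------------------------------------------------------
# corruption injectors
# ---------------------------------------------------------------------------

def inject_artifacts(
    rec: Recording,
    windows: list[int],
    magnitude: float,
    window_s: float = 30.0,
    channel: str | None = None,
) -> Recording:
    """Add square-pulse excursions of ``magnitude`` in the listed 30-s windows.

    The pulse occupies the middle half of each window: movement artifacts are
    brief excursions, and a pulse spanning an entire window would vanish under
    the within-window mean subtraction the detector applies.
    """
    samples = rec.samples.copy()
    col = rec.channel_labels.index(channel) if channel else 0
    wlen = int(round(window_s * rec.rate))
    n_win = rec.n_samples // wlen
    for w in windows:
        if not 0 <= w < n_win:
            raise ConfigError(f"artifact window {w} outside [0, {n_win})")
        i0 = w * wlen + wlen // 4
        samples[i0 : i0 + wlen // 2, col] += magnitude
    return Recording(
        samples=samples,
        rate=rec.rate,
        channel_labels=list(rec.channel_labels),
        start_offset_s=rec.start_offset_s,
    )


def inject_line_noise(
    rec: Recording, freq_hz: float = 60.0, amplitude: float = 1.0
) -> Recording:
    """Add a pure sinusoid (mains hum) across the whole recording."""
    if freq_hz >= rec.rate / 2.0:
        raise ConfigError(f"line frequency {freq_hz:g} Hz above Nyquist")
    t = np.arange(rec.n_samples) / rec.rate
    tone = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return Recording(
        samples=rec.samples + tone[:, None],
        rate=rec.rate,
        channel_labels=list(rec.channel_labels),
        start_offset_s=rec.start_offset_s,
    )
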