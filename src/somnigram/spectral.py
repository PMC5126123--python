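"""Morlet-wavelet time-frequency decomposition and whole-night baselining.

The decomposition covers 0.1–150 Hz on a log-spaced grid, with the wavelet
cycle count increasing linearly over bin index from 3 at the lowest frequency
to 30 at the highest, so each frequency integrates a different window — 30 s
at 0.1 Hz down to 0.2 s at 150 Hz.  Power is ``W·conj(W)`` converted to dB by
``10·log10``, and the per-frequency whole-night mean over artifact-free time
is subtracted to yield *relative* power, which is what both the display and
the staging features consume.

Large movement artifacts are tagged (never deleted) by a 30-s-window
amplitude statistic exceeding 5 SDs of all *other* windows; line noise is
masked for display only by substituting the average of the four neighbouring
clean bins; a 40-s moving average smooths the display spectrogram only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import oaconvolve

from .errors import (
    ConfigError,
    ContractError,
    InputTooShortError,
    InsufficientDataError,
)
from .io_formats import Recording

POWER_FLOOR = 1e-12  # power floor before log so silence maps to -120 dB

DEFAULT_F_MIN = 0.1
DEFAULT_F_MAX = 150.0
DEFAULT_N_BINS = 100
DEFAULT_STEP_S = 0.5
DEFAULT_ARTIFACT_WINDOW_S = 30.0
DEFAULT_ARTIFACT_K_SD = 5.0
DEFAULT_SMOOTH_S = 40.0
DEFAULT_LINE_BANDS = ((50.0, 70.0),)

CYCLES_MIN = 3.0
CYCLES_MAX = 30.0

#: ratio of wavelet support to Gaussian envelope SD — the envelope decays to
#: ~e^-6 at the truncation edges
SUPPORT_OVER_SIGMA = 7.0


@dataclass
class FrequencyGrid:
    """Log-spaced analysis frequencies with per-bin wavelet cycle counts."""

    freqs_hz: np.ndarray
    cycles: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.freqs_hz.size

    def window_s(self) -> np.ndarray:
        """Effective wavelet support per bin, ``cycles / freq`` seconds."""
        return self.cycles / self.freqs_hz

    def bins_in_band(self, lo: float, hi: float, upper_inclusive: bool = False) -> np.ndarray:
        """Indices of bins whose center lies in ``[lo, hi)`` (or ``[lo, hi]``)."""
        if upper_inclusive:
            sel = (self.freqs_hz >= lo) & (self.freqs_hz <= hi)
        else:
            sel = (self.freqs_hz >= lo) & (self.freqs_hz < hi)
        return np.flatnonzero(sel)


@dataclass
class Spectrogram:
    """Time × frequency matrix of dB power with processing-stage provenance.

    ``stage_tag`` tracks the pipeline stage (``raw_db`` → ``baselined`` →
    ``smoothed`` / ``line_masked``) so downstream consumers can enforce their
    contracts (e.g. features must read the baselined *unsmoothed* values).
    ``edge_flags[t, f]`` marks steps whose wavelet window overran the data for
    that frequency (computed on the zero-padded signal).
    """

    values_db: np.ndarray
    step_s: float
    grid: FrequencyGrid
    stage_tag: str = "raw_db"
    edge_flags: np.ndarray | None = None
    start_offset_s: float = 0.0

    @property
    def n_steps(self) -> int:
        return self.values_db.shape[0]

    def step_centers_s(self) -> np.ndarray:
        return self.start_offset_s + (np.arange(self.n_steps) + 0.5) * self.step_s


@dataclass
class ArtifactMask:
    """Per-30-s-window artifact flags from the leave-one-out 5-SD rule."""

    window_s: float
    flagged: np.ndarray
    per_window_stat: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.flagged.size

    def step_is_artifact(self, step_centers_s: np.ndarray) -> np.ndarray:
        """Flag time steps whose containing window is flagged.

        Steps past the last complete window are treated as clean.
        """
        idx = np.floor(step_centers_s / self.window_s).astype(int)
        inside = idx < self.n_windows
        out = np.zeros(step_centers_s.size, dtype=bool)
        out[inside] = self.flagged[idx[inside]]
        return out


@dataclass
class BaselineSpectrum:
    """Per-frequency mean dB over artifact-free (and edge-clean) steps."""

    mean_db: np.ndarray
    n_steps_used: int


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def build_frequency_grid(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    n_bins: int = DEFAULT_N_BINS,
) -> FrequencyGrid:
    """Log-spaced frequencies with cycles linear in bin index from 3 to 30."""
    if f_min <= 0:
        raise ConfigError(f"f_min must be > 0 for log spacing, got {f_min}")
    if not f_min < f_max:
        raise ConfigError(f"need f_min < f_max, got {f_min} >= {f_max}")
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    freqs = np.geomspace(f_min, f_max, n_bins)
    cycles = np.linspace(CYCLES_MIN, CYCLES_MAX, n_bins)
    return FrequencyGrid(freqs_hz=freqs, cycles=cycles)


# ---------------------------------------------------------------------------
# wavelet transform
# ---------------------------------------------------------------------------

def _morlet_kernel(freq: float, cycles: float, rate: float) -> np.ndarray:
    """Complex Morlet kernel truncated to its support ``cycles/freq`` seconds.

    The Gaussian envelope SD is support/7; the kernel is L1-normalised on the
    envelope so a unit-amplitude sinusoid at ``freq`` yields |W| ≈ 1/2
    independent of window length (any linear normalisation preserves the dB
    relations the pipeline relies on).
    """
    support_s = cycles / freq
    half = int(round(support_s * rate / 2))
    tau = np.arange(-half, half + 1) / rate
    sigma = support_s / SUPPORT_OVER_SIGMA
    envelope = np.exp(-(tau**2) / (2 * sigma**2))
    kernel = envelope * np.exp(2j * np.pi * freq * tau)
    return kernel / envelope.sum()


def wavelet_spectrogram(
    rec: Recording,
    channel: str,
    grid: FrequencyGrid | None = None,
    step_s: float = DEFAULT_STEP_S,
) -> Spectrogram:
    """Morlet spectrogram of one channel at 0.5-s steps, in dB.

    For each step center t and bin f the complex coefficient is the inner
    product of the signal with a Morlet kernel of support ``cycles(f)/f``
    seconds centered at t (evaluated via FFT convolution on the zero-padded
    signal); power = W·conj(W), floored at 1e-12, then ``10·log10``.
    """
    if grid is None:
        grid = build_frequency_grid()
    x = rec.channel(channel)
    n = x.size
    longest = float(np.max(grid.window_s()))
    if rec.duration_s < longest:
        raise InputTooShortError(
            f"recording of {rec.duration_s:g} s is shorter than the longest "
            f"wavelet window ({longest:g} s)"
        )
    n_steps = int(np.floor(rec.duration_s / step_s))
    centers = np.minimum(
        (np.round((np.arange(n_steps) + 0.5) * step_s * rec.rate)).astype(int), n - 1
    )
    values = np.empty((n_steps, grid.n_bins))
    edges = np.zeros((n_steps, grid.n_bins), dtype=bool)
    for j in range(grid.n_bins):
        kernel = _morlet_kernel(grid.freqs_hz[j], grid.cycles[j], rec.rate)
        # correlation with the kernel == convolution with its reversed conjugate
        w = oaconvolve(x, np.conj(kernel[::-1]), mode="same")
        wc = w[centers]
        power = np.maximum((wc * np.conj(wc)).real, POWER_FLOOR)
        values[:, j] = 10.0 * np.log10(power)
        half = (kernel.size - 1) // 2
        edges[:, j] = (centers - half < 0) | (centers + half >= n)
    return Spectrogram(
        values_db=values,
        step_s=step_s,
        grid=grid,
        stage_tag="raw_db",
        edge_flags=edges,
        start_offset_s=rec.start_offset_s,
    )


# ---------------------------------------------------------------------------
# artifact detection
# ---------------------------------------------------------------------------

def detect_artifact_windows(
    rec: Recording,
    channel: str,
    window_s: float = DEFAULT_ARTIFACT_WINDOW_S,
    k_sd: float = DEFAULT_ARTIFACT_K_SD,
) -> ArtifactMask:
    """Tag 30-s windows whose amplitude statistic exceeds 5 SDs of the rest.

    Each complete window's statistic is ``max|x − mean(x)|`` over the window;
    window w is flagged iff its statistic strictly exceeds
    ``mean + k_sd·SD`` of the statistics of all *other* windows
    (leave-one-out, sample SD).
    """
    x = rec.channel(channel)
    wlen = int(round(window_s * rec.rate))
    n_win = x.size // wlen
    if n_win < 3:
        raise InsufficientDataError(
            f"need >= 3 complete {window_s:g}-s windows, got {n_win}"
        )
    windows = x[: n_win * wlen].reshape(n_win, wlen)
    stats = np.abs(windows - windows.mean(axis=1, keepdims=True)).max(axis=1)
    s1 = stats.sum()
    s2 = (stats**2).sum()
    m = n_win - 1
    mean_loo = (s1 - stats) / m
    # unbiased variance of the other m values, guarded against tiny negatives
    var_loo = np.maximum((s2 - stats**2 - m * mean_loo**2) / (m - 1), 0.0)
    thresh = mean_loo + k_sd * np.sqrt(var_loo)
    flagged = stats > thresh
    return ArtifactMask(window_s=window_s, flagged=flagged, per_window_stat=stats)


# ---------------------------------------------------------------------------
# baselining
# ---------------------------------------------------------------------------

def baseline_valid_steps(spec: Spectrogram, mask: ArtifactMask) -> np.ndarray:
    """Boolean (n_steps, n_freqs): steps usable for the baseline mean.

    A step contributes at a frequency when its containing artifact window is
    unflagged and its wavelet window did not overrun the data there.
    """
    artifact = mask.step_is_artifact(spec.step_centers_s() - spec.start_offset_s)
    valid = np.broadcast_to(~artifact[:, None], spec.values_db.shape).copy()
    if spec.edge_flags is not None:
        valid &= ~spec.edge_flags
    return valid


def compute_baseline_spectrum(spec: Spectrogram, mask: ArtifactMask) -> BaselineSpectrum:
    """Per-frequency mean dB over artifact-free steps (whole-night baseline)."""
    if spec.stage_tag != "raw_db":
        raise ContractError(f"baseline must be computed on raw_db, got {spec.stage_tag!r}")
    artifact = mask.step_is_artifact(spec.step_centers_s() - spec.start_offset_s)
    if artifact.all():
        import warnings

        warnings.warn("all windows flagged as artifact; baseline falls back to all steps")
        artifact = np.zeros_like(artifact)
    valid = np.broadcast_to(~artifact[:, None], spec.values_db.shape).copy()
    if spec.edge_flags is not None:
        valid &= ~spec.edge_flags
    counts = valid.sum(axis=0)
    mean_db = np.empty(spec.grid.n_bins)
    for j in range(spec.grid.n_bins):
        if counts[j] > 0:
            mean_db[j] = spec.values_db[valid[:, j], j].mean()
        else:  # every step edge-flagged at this frequency: ignore edge flags
            mean_db[j] = spec.values_db[~artifact, j].mean()
    return BaselineSpectrum(mean_db=mean_db, n_steps_used=int((~artifact).sum()))


def subtract_baseline(spec: Spectrogram, baseline: BaselineSpectrum) -> Spectrogram:
    """Relative power: subtract the per-frequency whole-night mean."""
    if spec.stage_tag != "raw_db":
        raise ContractError(f"can only baseline a raw_db spectrogram, got {spec.stage_tag!r}")
    return replace(
        spec, values_db=spec.values_db - baseline.mean_db[None, :], stage_tag="baselined"
    )


# ---------------------------------------------------------------------------
# display-only transforms
# ---------------------------------------------------------------------------

def mask_line_noise(
    spec: Spectrogram, bands: tuple[tuple[float, float], ...] = DEFAULT_LINE_BANDS
) -> Spectrogram:
    """Replace line-frequency bins by the mean of the 4 neighbouring bins.

    Display only — feature extraction must consume the unmasked spectrogram.
    """
    if spec.stage_tag not in ("baselined", "smoothed"):
        raise ContractError(
            f"line masking applies after baselining, got {spec.stage_tag!r}"
        )
    values = spec.values_db.copy()
    freqs = spec.grid.freqs_hz
    for lo, hi in bands:
        in_band = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if in_band.size == 0:
            continue
        below = np.flatnonzero(freqs < lo)
        above = np.flatnonzero(freqs > hi)
        if below.size < 2 or above.size < 2:
            raise ConfigError(
                f"line band [{lo}, {hi}] Hz needs 2 grid bins on each side"
            )
        ref = np.concatenate([below[-2:], above[:2]])
        values[:, in_band] = values[:, ref].mean(axis=1, keepdims=True)
    return replace(spec, values_db=values, stage_tag="line_masked")


def smooth_time(spec: Spectrogram, window_s: float = DEFAULT_SMOOTH_S) -> Spectrogram:
    """Centered moving average over time (display spectrogram only)."""
    if spec.stage_tag not in ("baselined", "line_masked"):
        raise ContractError(f"smoothing applies after baselining, got {spec.stage_tag!r}")
    w = max(int(round(window_s / spec.step_s)), 1)
    kernel = np.ones(w)
    counts = np.convolve(np.ones(spec.n_steps), kernel, mode="same")
    values = np.empty_like(spec.values_db)
    for j in range(spec.values_db.shape[1]):
        values[:, j] = np.convolve(spec.values_db[:, j], kernel, mode="same") / counts
    return replace(spec, values_db=values, stage_tag="smoothed")


def dominant_frequency(spec: Spectrogram) -> np.ndarray:
    """Per step, the frequency with maximal relative power (ties → lowest).

    Requires the *baselined, unsmoothed* spectrogram; returns an
    ``(n_steps, 2)`` array of (step index, frequency in Hz).
    """
    if spec.stage_tag != "baselined":
        raise ContractError(
            f"dominant frequency is defined on the baselined unsmoothed "
            f"spectrogram, got {spec.stage_tag!r}"
        )
    idx = np.argmax(spec.values_db, axis=1)  # first max → lowest frequency on ties
    return np.column_stack([np.arange(spec.n_steps), spec.grid.freqs_hz[idx]])


def export_spectrogram_csv(spec: Spectrogram, path: str) -> None:
    """Flat CSV export: one row per (time step, frequency bin)."""
    import pandas as pd

    t = spec.step_centers_s()
    tt, ff = np.meshgrid(t, spec.grid.freqs_hz, indexing="ij")
    pd.DataFrame(
        {
            "time_s": tt.ravel(),
            "freq_hz": ff.ravel(),
            "value_db": spec.values_db.ravel(),
        }
    ).to_csv(path, index=False)
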