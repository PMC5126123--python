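"""Readers, writers and alignment for EEG, EDA and hypnogram streams.

EEG arrives either as EDF (the de-facto polysomnography container) or as a
long-format numeric CSV; wrist electrodermal activity (EDA) arrives as a
single-column CSV of skin conductance in μS.  Hypnograms are read and written
as a three-column CSV (``epoch_index,onset_s,stage``) over the fixed five-stage
alphabet Wake / Light / HiDeep / LoDeep / REM.

All time offsets are seconds from session zero; the two recording devices are
assumed to share t=0 ("approximately synchronized" start), so alignment is a
truncation to the overlapping interval, never a resynchronisation.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    EmptyInputError,
    FormatError,
    ParseError,
)

STAGES = ("Wake", "Light", "HiDeep", "LoDeep", "REM")
"""The five-stage alphabet, bit-exact strings used in hypnogram files."""

DEFAULT_EPOCH_S = 30.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Raw multichannel EEG samples.

    Parameters
    ----------
    samples
        ``(n_samples, n_channels)`` float array, arbitrary amplitude units.
    rate
        Sampling rate in samples/second (positive, finite).
    channel_labels
        Unique label per channel, e.g. ``["FP1", "FP2", "FF"]``.
    start_offset_s
        Seconds from session zero at which the first sample was taken.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] < 1:
            raise EmptyInputError("recording has no samples")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise FormatError(f"sampling rate must be finite and positive, got {self.rate}")
        if len(self.channel_labels) != self.samples.shape[1]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError(f"duplicate channel labels: {self.channel_labels}")
        if self.start_offset_s < 0:
            raise FormatError("start_offset_s must be >= 0")
        if not np.isfinite(self.samples).all():
            raise FormatError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector for *label*."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ConfigError(
                f"unknown channel {label!r}; available: {self.channel_labels}"
            ) from None
        return self.samples[:, idx]


@dataclass
class EDASeries:
    """Skin conductance time series in μS."""

    values: np.ndarray
    rate: float
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise EmptyInputError("EDA series is empty")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise FormatError(f"EDA rate must be finite and positive, got {self.rate}")
        if not np.isfinite(self.values).all():
            raise FormatError("EDA series contains non-finite values")
        if (self.values < 0).any():
            raise FormatError("EDA values must be >= 0 (reader clips on load)")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from session zero."""
        return self.start_offset_s + np.arange(self.values.size) / self.rate


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels over the five-stage alphabet."""

    stages: list[str]
    epoch_s: float = DEFAULT_EPOCH_S
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        if len(self.stages) < 1:
            raise EmptyInputError("hypnogram has no epochs")
        if self.epoch_s <= 0:
            raise FormatError("epoch_s must be > 0")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise FormatError(f"unknown stage labels {bad}; expected one of {STAGES}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def onsets(self) -> np.ndarray:
        return self.start_offset_s + np.arange(self.n_epochs) * self.epoch_s


@dataclass
class LoadReport:
    """Bookkeeping emitted by the readers (resampling, clipped values)."""

    notes: list[str] = field(default_factory=list)
    n_clipped: int = 0
    resampled: bool = False


# ---------------------------------------------------------------------------
# EEG readers
# ---------------------------------------------------------------------------

def read_eeg_edf(path: str | os.PathLike) -> tuple[Recording, LoadReport]:
    """Read an EDF file into a :class:`Recording`.

    Channels sampled at unequal rates are linearly resampled up to the maximum
    rate (recorded in the load report); EDF header labels become channel
    labels.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"input not found: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"not an EDF file (zero bytes at offset 0): {path}")
    report = LoadReport()
    try:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except FormatError:
        raise
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"unreadable EDF (failed near byte offset 0–256): {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise EmptyInputError(f"EDF contains zero channels: {path}")
    native = raw._raw_extras[0].get("n_samps") if raw._raw_extras else None
    if native is not None and len(set(int(n) for n in np.atleast_1d(native)[: len(raw.ch_names)])) > 1:
        report.resampled = True
        report.notes.append(
            "channels had unequal sampling rates; all resampled to "
            f"{raw.info['sfreq']:g} Hz by linear interpolation"
        )
    data = raw.get_data().T  # (n_samples, n_channels), volts
    if not np.isfinite(data).all():
        raise FormatError(f"EDF contains non-finite samples: {path}")
    rec = Recording(
        samples=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )
    return rec, report


def _read_numeric_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a comma-separated numeric table, auto-detecting one header row."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"input not found: {path}")
    if os.path.getsize(path) == 0:
        raise EmptyInputError(f"empty file: {path}")
    with open(path) as fh:
        first = fh.readline()
    header: int | None = None
    for tok in first.strip().split(","):
        try:
            float(tok)
        except ValueError:
            header = 0
            break
    df = pd.read_csv(path, header=header, dtype=str, skip_blank_lines=True)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows: {path}")
    return df


def _to_float_matrix(df: pd.DataFrame, path: str) -> np.ndarray:
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        rows = np.flatnonzero(bad.any(axis=1))
        raise ParseError(
            f"{path}: non-numeric or non-finite cells in rows {rows[:10].tolist()}"
            + ("..." if rows.size > 10 else "")
            + f" (first offending row {rows[0]})"
        )
    return values


def read_eeg_csv(
    path: str | os.PathLike,
    rate: float,
    columns: list[str] | None = None,
) -> tuple[Recording, LoadReport]:
    """Read long-format EEG CSV (samples × channels) at a caller-supplied rate.

    ``columns`` selects and orders channels by header name; when the file has
    no header the labels default to ``ch0..chN``.
    """
    df = _read_numeric_csv(path)
    if df.columns.dtype == object and not all(isinstance(c, int) for c in df.columns):
        labels = [str(c) for c in df.columns]
    else:
        labels = [f"ch{i}" for i in range(df.shape[1])]
        df.columns = labels
    if columns is not None:
        missing = [c for c in columns if c not in labels]
        if missing:
            raise ConfigError(f"{path}: configured columns {missing} absent; file has {labels}")
        df = df[list(columns)]
        labels = list(columns)
    values = _to_float_matrix(df, os.fspath(path))
    return Recording(samples=values, rate=float(rate), channel_labels=labels), LoadReport()


def read_eda_csv(path: str | os.PathLike, rate: float) -> tuple[EDASeries, LoadReport]:
    """Read a single-column EDA CSV; negative values are clipped to 0 μS."""
    df = _read_numeric_csv(path)
    if df.shape[1] != 1:
        df = df.iloc[:, :1]
    values = _to_float_matrix(df, os.fspath(path)).ravel()
    report = LoadReport()
    n_neg = int((values < 0).sum())
    if n_neg:
        values = np.clip(values, 0.0, None)
        report.n_clipped = n_neg
        report.notes.append(f"clipped {n_neg} negative EDA samples to 0 μS")
    return EDASeries(values=values, rate=float(rate)), report


# ---------------------------------------------------------------------------
# channel derivation and stream alignment
# ---------------------------------------------------------------------------

def derive_difference_channel(
    rec: Recording, a: str, b: str, out_label: str = "FF"
) -> Recording:
    """Append the sample-wise difference channel ``a − b`` (e.g. FP1−FP2 = FF).

    The forehead-forehead difference suppresses signals common to both
    forehead electrodes, notably >30 Hz activity picked up at a shared mastoid
    reference.
    """
    if out_label in rec.channel_labels:
        raise ConfigError(f"output label {out_label!r} collides with an existing channel")
    xa = rec.channel(a)
    xb = rec.channel(b)
    if a == b:
        warnings.warn(f"difference of channel {a!r} with itself is identically zero")
    samples = np.column_stack([rec.samples, xa - xb])
    return Recording(
        samples=samples,
        rate=rec.rate,
        channel_labels=rec.channel_labels + [out_label],
        start_offset_s=rec.start_offset_s,
    )


def align_streams(rec: Recording, eda: EDASeries) -> tuple[Recording, EDASeries]:
    """Truncate both streams to their overlapping interval.

    Both streams are re-referenced so the overlap starts at session zero.
    With the default zero offsets this simply truncates to the shorter
    duration.
    """
    lo = max(rec.start_offset_s, eda.start_offset_s)
    hi = min(rec.start_offset_s + rec.duration_s, eda.start_offset_s + eda.duration_s)
    if hi <= lo:
        raise AlignmentError(
            "streams do not overlap: EEG covers "
            f"[{rec.start_offset_s:g}, {rec.start_offset_s + rec.duration_s:g}] s, "
            f"EDA covers [{eda.start_offset_s:g}, {eda.start_offset_s + eda.duration_s:g}] s"
        )
    i0 = int(round((lo - rec.start_offset_s) * rec.rate))
    i1 = int(round((hi - rec.start_offset_s) * rec.rate))
    j0 = int(round((lo - eda.start_offset_s) * eda.rate))
    j1 = int(round((hi - eda.start_offset_s) * eda.rate))
    rec_out = replace(rec, samples=rec.samples[i0:i1], start_offset_s=0.0)
    eda_out = replace(eda, values=eda.values[j0:j1], start_offset_s=0.0)
    return rec_out, eda_out


# ---------------------------------------------------------------------------
# hypnogram I/O
# ---------------------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path: str | os.PathLike) -> None:
    """Write CSV with columns ``epoch_index,onset_s,stage`` (0-based epochs)."""
    buf = io.StringIO()
    buf.write("epoch_index,onset_s,stage\n")
    for i, stage in enumerate(h.stages):
        onset = h.start_offset_s + i * h.epoch_s
        buf.write(f"{i},{onset:g},{stage}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    """Read the CSV written by :func:`write_hypnogram`; round-trip is exact."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"input not found: {path}")
    df = pd.read_csv(path)
    required = {"epoch_index", "onset_s", "stage"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: hypnogram CSV needs columns {sorted(required)}")
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: hypnogram has no epochs")
    stages = [str(s) for s in df["stage"]]
    bad = sorted({s for s in stages if s not in STAGES})
    if bad:
        raise FormatError(f"{path}: unknown stage strings {bad}; expected {STAGES}")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if len(onsets) > 1:
        epoch_s = float(onsets[1] - onsets[0])
    else:
        epoch_s = DEFAULT_EPOCH_S
    return Hypnogram(stages=stages, epoch_s=epoch_s, start_offset_s=float(onsets[0]))
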