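"""Electrodermal activity quantified against the hypnogram.

Four per-night statistics characterise how skin conductance behaves in each
sleep stage:

* per-stage mean EDA and the ratio of each stage's mean to the pooled mean of
  all other stages, gated at 0.25 μS (below that level the ratio of means can
  look large with no actual EDA peak);
* the quarter of the post-onset night containing the highest mean EDA;
* for sustained stage bouts (≥8 min, tolerating one or two isolated
  single-epoch excursions), the change from the first to the last minute;
* the percentage of time EDA is rising (first difference above a small
  positive threshold), per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError
from .io_formats import STAGES, EDASeries, Hypnogram
from .staging import compute_sleep_metrics

DEFAULT_GATE_US = 0.25
DEFAULT_DERIV_THRESHOLD = 0.0001  # μS per sample interval at the native rate
DEFAULT_BOUT_MIN_MIN = 8.0
DEFAULT_MAX_EXCURSIONS = 2


@dataclass
class EDAStageStats:
    """Container for the four EDA-by-stage statistics.

    Stages absent from the night (or with too few samples) carry ``None`` in
    the corresponding mapping rather than raising.
    """

    stage_means: dict[str, float | None] = field(default_factory=dict)
    eligible: bool | None = None
    ratios: dict[str, float | None] = field(default_factory=dict)
    max_quarter: int | None = None
    bout_deltas: dict[str, float | None] = field(default_factory=dict)
    rising_fraction: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage_means": self.stage_means,
            "eligible": self.eligible,
            "ratios": self.ratios,
            "max_quarter": self.max_quarter,
            "bout_deltas": self.bout_deltas,
            "rising_fraction": self.rising_fraction,
        }


def _sample_stages(eda: EDASeries, h: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
    """Stage label index per EDA sample (samples beyond the hypnogram dropped).

    Samples are assigned to epochs by left-edge containment in
    ``[onset, onset + epoch_s)``.
    """
    t = eda.times() - h.start_offset_s
    epoch_idx = np.floor(t / h.epoch_s).astype(int)
    keep = (epoch_idx >= 0) & (epoch_idx < h.n_epochs)
    stage_of_epoch = np.array([STAGES.index(s) for s in h.stages])
    return np.flatnonzero(keep), stage_of_epoch[epoch_idx[keep]]


def stage_means_and_ratios(
    eda: EDASeries, h: Hypnogram, gate_uS: float = DEFAULT_GATE_US
) -> EDAStageStats:
    """Per-stage mean EDA and the stage-vs-rest mean ratio, gated at 0.25 μS.

    ``eligible`` is True when the maximum stage mean exceeds the gate; ratios
    are only computed for eligible nights.
    """
    keep, stage_idx = _sample_stages(eda, h)
    values = eda.values[keep]
    if values.size == 0:
        raise EmptyInputError("no EDA samples fall within the hypnogram span")
    stats = EDAStageStats()
    means: dict[str, float | None] = {}
    for k, stage in enumerate(STAGES):
        sel = stage_idx == k
        means[stage] = float(values[sel].mean()) if sel.any() else None
    stats.stage_means = means
    defined = [m for m in means.values() if m is not None]
    stats.eligible = bool(max(defined) > gate_uS)
    ratios: dict[str, float | None] = {s: None for s in STAGES}
    if stats.eligible:
        for k, stage in enumerate(STAGES):
            sel = stage_idx == k
            rest = ~sel
            if sel.any() and rest.any() and values[rest].mean() > 0:
                ratios[stage] = float(values[sel].mean() / values[rest].mean())
    stats.ratios = ratios
    return stats


def quarter_of_max_eda(eda: EDASeries, h: Hypnogram) -> int | None:
    """Quarter (1–4) of the post-onset night with the highest mean EDA.

    The post-onset span is split into four equal-duration quarters; ties go
    to the earliest quarter.  Returns ``None`` when sleep onset is undefined.
    """
    metrics = compute_sleep_metrics(h)
    if metrics.sleep_onset_latency_min is None:
        return None
    onset_s = h.start_offset_s + metrics.sleep_onset_latency_min * 60.0
    end_s = h.start_offset_s + h.duration_s
    t = eda.times()
    keep = (t >= onset_s) & (t < end_s)
    if not keep.any():
        return None
    span = (end_s - onset_s) / 4.0
    q_idx = np.minimum(np.floor((t[keep] - onset_s) / span).astype(int), 3)
    values = eda.values[keep]
    q_means = np.array(
        [values[q_idx == q].mean() if (q_idx == q).any() else -np.inf for q in range(4)]
    )
    return int(np.argmax(q_means)) + 1


def extract_stage_bouts(
    h: Hypnogram,
    stage: str,
    min_duration_min: float = DEFAULT_BOUT_MIN_MIN,
    max_excursions: int = DEFAULT_MAX_EXCURSIONS,
) -> list[tuple[float, float]]:
    """Sustained bouts of one stage as ``[start_s, end_s)`` intervals.

    A bout is a maximal run of the stage tolerating up to ``max_excursions``
    isolated single-epoch interruptions by other stages; interruptions count
    toward the duration but a bout must start and end on the target stage.
    Only bouts lasting ``min_duration_min`` minutes or more qualify.
    """
    is_stage = np.array([s == stage for s in h.stages])
    n = h.n_epochs
    bouts: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not is_stage[i]:
            i += 1
            continue
        start = i
        end = i  # inclusive index of last target-stage epoch
        excursions = 0
        j = i + 1
        while j < n:
            if is_stage[j]:
                end = j
                j += 1
            elif (
                excursions < max_excursions
                and j + 1 < n
                and is_stage[j + 1]
            ):
                excursions += 1  # single isolated excursion epoch
                j += 1
            else:
                break
        bouts.append((start, end))
        i = j
    out = []
    for start, end in bouts:
        dur_s = (end - start + 1) * h.epoch_s
        if dur_s >= min_duration_min * 60.0:
            out.append(
                (
                    h.start_offset_s + start * h.epoch_s,
                    h.start_offset_s + (end + 1) * h.epoch_s,
                )
            )
    return out


def bout_onset_offset_delta(
    eda: EDASeries,
    h: Hypnogram,
    stage: str,
    min_duration_min: float = DEFAULT_BOUT_MIN_MIN,
    max_excursions: int = DEFAULT_MAX_EXCURSIONS,
) -> tuple[float | None, list[float]]:
    """Mean (last-minute − first-minute) EDA over qualifying stage bouts.

    Returns ``(aggregate mean, per-bout deltas)``; the aggregate is ``None``
    when no bout qualifies.  Per-bout values are retained for downstream
    group analysis.
    """
    bouts = extract_stage_bouts(h, stage, min_duration_min, max_excursions)
    t = eda.times()
    deltas: list[float] = []
    for start_s, end_s in bouts:
        first = (t >= start_s) & (t < start_s + 60.0)
        last = (t >= end_s - 60.0) & (t < end_s)
        if not (first.any() and last.any()):
            continue
        deltas.append(float(eda.values[last].mean() - eda.values[first].mean()))
    if not deltas:
        return None, []
    return float(np.mean(deltas)), deltas


def rising_time_fraction(
    eda: EDASeries,
    h: Hypnogram,
    deriv_threshold: float = DEFAULT_DERIV_THRESHOLD,
) -> dict[str, float | None]:
    """Percentage of time EDA is rising, per stage.

    First differences on the native sampling grid (μS per sample interval); a
    difference belongs to the stage of its left sample.  Stages with fewer
    than two samples are ``None``.
    """
    keep, stage_idx = _sample_stages(eda, h)
    values = eda.values[keep]
    if values.size < 2:
        raise EmptyInputError("need at least 2 EDA samples inside the hypnogram")
    diffs = np.diff(values)
    left_stage = stage_idx[:-1]
    out: dict[str, float | None] = {}
    for k, stage in enumerate(STAGES):
        sel = left_stage == k
        n_sel = int(sel.sum())
        if n_sel < 1 or int((stage_idx == k).sum()) < 2:
            out[stage] = None
            continue
        out[stage] = float(100.0 * (diffs[sel] > deriv_threshold).sum() / n_sel)
    return out


def compute_eda_stage_stats(
    eda: EDASeries,
    h: Hypnogram,
    gate_uS: float = DEFAULT_GATE_US,
    deriv_threshold: float = DEFAULT_DERIV_THRESHOLD,
    bout_min_min: float = DEFAULT_BOUT_MIN_MIN,
    max_excursions: int = DEFAULT_MAX_EXCURSIONS,
) -> EDAStageStats:
    """All four EDA statistics in one pass (the ``eda`` CLI command's payload)."""
    stats = stage_means_and_ratios(eda, h, gate_uS)
    stats.max_quarter = quarter_of_max_eda(eda, h)
    stats.bout_deltas = {
        s: bout_onset_offset_delta(eda, h, s, bout_min_min, max_excursions)[0]
        for s in STAGES
    }
    stats.rising_fraction = rising_time_fraction(eda, h, deriv_threshold)
    return stats
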