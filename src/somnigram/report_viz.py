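"""Whole-night sleep report rendering.

The report stacks, top to bottom: the smoothed, line-masked, baselined
spectrogram on a log-frequency axis with a symmetric diverging colour scale;
the dominant-frequency dot matrix (from the *unsmoothed* baselined
spectrogram); an optional EDA trace; and the hypnogram with Wake at the top
and Lo Deep at the bottom.  Artifact windows are marked with vertical lines.
Rendering is deterministic for fixed inputs (byte-identical SVG) and never
mutates the analysis objects it consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ContractError, EmptyInputError
from .io_formats import EDASeries, Hypnogram
from .spectral import ArtifactMask, Spectrogram

# stage order on the hypnogram y-axis, top to bottom
STAGE_ORDER = ("Wake", "REM", "Light", "HiDeep", "LoDeep")

_SVG_SALT = "somnigram"  # fixed hashsalt so SVG ids are reproducible


@dataclass
class ReportLayout:
    """Panel sizes, colour limits and output options for the report figure."""

    color_limit_db: float = 8.0  # symmetric about 0 dB
    figure_width_in: float = 11.0
    panel_height_in: float = 1.8
    dot_size: float = 1.0
    colormap: str = "RdBu_r"  # perceptually reasonable diverging map
    extra: dict = field(default_factory=dict)


def _deterministic_rc():
    return matplotlib.rc_context({"svg.hashsalt": _SVG_SALT, "figure.dpi": 100})


def _save(fig, path: str) -> None:
    if str(path).endswith(".svg"):
        fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)


def render_sleep_report(
    spec_display: Spectrogram,
    dots: np.ndarray,
    h: Hypnogram,
    eda: EDASeries | None = None,
    mask: ArtifactMask | None = None,
    layout: ReportLayout | None = None,
    path: str | None = None,
):
    """Render the stacked whole-night report; returns the Figure.

    ``spec_display`` must be the smoothed (and usually line-masked) display
    spectrogram; ``dots`` the (step, freq) dominant-frequency pairs from the
    unsmoothed baselined spectrogram.  All inputs must cover the same span to
    within one epoch.
    """
    layout = layout or ReportLayout()
    spans = [spec_display.n_steps * spec_display.step_s, h.duration_s]
    if eda is not None:
        spans.append(eda.duration_s)
    if max(spans) - min(spans) > h.epoch_s:
        raise ContractError(
            f"input spans differ by more than one epoch: {spans} s"
        )
    if spec_display.stage_tag not in ("smoothed", "line_masked"):
        raise ContractError(
            f"report spectrogram panel expects the display (smoothed/masked) "
            f"spectrogram, got {spec_display.stage_tag!r}"
        )
    n_panels = 4 if eda is not None else 3
    with _deterministic_rc():
        fig, axes = plt.subplots(
            n_panels,
            1,
            sharex=True,
            figsize=(layout.figure_width_in, layout.panel_height_in * n_panels),
            constrained_layout=True,
        )
        duration_h = spec_display.n_steps * spec_display.step_s / 3600.0
        t_h = spec_display.step_centers_s() / 3600.0

        ax = axes[0]
        ax.pcolormesh(
            t_h,
            spec_display.grid.freqs_hz,
            spec_display.values_db.T,
            cmap=layout.colormap,
            vmin=-layout.color_limit_db,
            vmax=layout.color_limit_db,
            shading="nearest",
            rasterized=True,
        )
        ax.set_yscale("log")
        ax.set_ylabel("frequency (Hz)")
        if mask is not None:
            for w in np.flatnonzero(mask.flagged):
                ax.axvline((w + 0.5) * mask.window_s / 3600.0, color="cyan", lw=0.8)

        render_dominant_dots(dots, spec_display, ax=axes[1], layout=layout)

        idx = 2
        if eda is not None:
            axes[idx].plot(eda.times() / 3600.0, eda.values, color="tab:orange", lw=0.8)
            axes[idx].set_ylabel("EDA (μS)")
            idx += 1

        render_hypnogram_panel(h, ax=axes[idx])
        axes[idx].set_xlabel("time (h)")
        for ax in axes:
            ax.set_xlim(0.0, duration_h)
        if path is not None:
            _save(fig, str(path))
    return fig


def render_dominant_dots(
    dots: np.ndarray,
    spec: Spectrogram | None = None,
    ax=None,
    layout: ReportLayout | None = None,
):
    """Dot matrix of the per-step dominant frequency on a log axis."""
    if dots is None or len(dots) == 0:
        raise EmptyInputError("no dominant-frequency dots to render")
    layout = layout or ReportLayout()
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(layout.figure_width_in, layout.panel_height_in))
    dots = np.asarray(dots)
    step_s = spec.step_s if spec is not None else 0.5
    t_h = (dots[:, 0] + 0.5) * step_s / 3600.0
    ax.scatter(t_h, dots[:, 1], s=layout.dot_size, c="k", marker=".")
    ax.set_yscale("log")
    if spec is not None:
        ax.set_ylim(spec.grid.freqs_hz[0], spec.grid.freqs_hz[-1])
    ax.set_ylabel("dominant freq (Hz)")
    return ax


def render_hypnogram_panel(h: Hypnogram, ax=None, layout: ReportLayout | None = None):
    """Step-plot hypnogram with Wake at the top and Lo Deep at the bottom."""
    if h.n_epochs == 0:
        raise EmptyInputError("empty hypnogram")
    layout = layout or ReportLayout()
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(layout.figure_width_in, layout.panel_height_in))
    level = {s: len(STAGE_ORDER) - 1 - i for i, s in enumerate(STAGE_ORDER)}
    y = np.array([level[s] for s in h.stages])
    t_h = (h.onsets()) / 3600.0
    ax.step(np.append(t_h, t_h[-1] + h.epoch_s / 3600.0), np.append(y, y[-1]),
            where="post", color="tab:blue", lw=1.0)
    ax.set_yticks([level[s] for s in STAGE_ORDER])
    ax.set_yticklabels(STAGE_ORDER)
    ax.set_ylim(-0.5, len(STAGE_ORDER) - 0.5)
    ax.set_ylabel("stage")
    return ax


def save_panel_svg(render_fn, path: str, *args, **kwargs) -> None:
    """Render one panel via ``render_fn`` and save deterministically as SVG."""
    with _deterministic_rc():
        fig, ax = plt.subplots(figsize=(8, 2))
        render_fn(*args, ax=ax, **kwargs)
        _save(fig, path)
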