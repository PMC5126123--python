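"""Unsupervised five-stage sleep scoring with a Gaussian-emission HMM.

Each 30-s epoch is summarised by a 5-dimensional observation vector y — the
mean relative dB power in five bands that roughly correspond to the five
stages (Lo Deep 0.1–1 Hz, Hi Deep 1–3 Hz, Light 10.5–16 Hz, REM 16–30 Hz,
Wake 37–47 Hz).  Stage dynamics are a first-order Markov chain with 5×5
row-stochastic transition matrix Q, where Q[i, j] = P(stage j at t+1 | stage
i at t); emissions R(y|j) are multivariate Gaussians N(μ_j, Σ_j).  All
parameters are fitted per night by Baum-Welch EM from a sticky initial Q
(diagonal 0.95, off-diagonal 0.0125), and the hypnogram is the Viterbi
maximum a posteriori state path.

The state→stage identity is frozen at initialisation: each state's emission
mean is seeded from the epochs whose strongest band is that state's band, so
no post-hoc relabelling is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    ContractError,
    EmptyInputError,
    InsufficientDataError,
    NumericalError,
)
from .io_formats import STAGES, Hypnogram
from .spectral import Spectrogram

# canonical band order: feature column k always means band k, and HMM state k
# is tied to stage k
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("LoDeep", 0.1, 1.0),
    ("HiDeep", 1.0, 3.0),
    ("Light", 10.5, 16.0),
    ("REM", 16.0, 30.0),
    ("Wake", 37.0, 47.0),
)

Q_INIT_DIAG = 0.95
Q_INIT_OFFDIAG = 0.0125

DEFAULT_EM_MAX_ITER = 100
DEFAULT_EM_TOL = 1e-6
DEFAULT_ONSET_MIN_RUN = 5  # consecutive non-Wake epochs (2.5 min) defining sleep onset

RIDGE_FRACTION = 1e-6  # per M-step diagonal ridge: 1e-6 · trace(Σ)/5


@dataclass
class BandSet:
    """Ordered scoring bands with half-open ``[lo, hi)`` Hz edges."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        intervals = sorted((lo, hi) for _, lo, hi in self.bands)
        for (_, h1), (l2, _) in zip(intervals, intervals[1:]):
            if l2 < h1:
                raise ConfigError(f"overlapping bands: {self.bands}")

    @property
    def labels(self) -> list[str]:
        return [name for name, _, _ in self.bands]

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class EpochFeatures:
    """n_epochs × n_bands matrix of mean relative dB per 30-s epoch."""

    y: np.ndarray
    epoch_s: float
    band_set: BandSet

    @property
    def n_epochs(self) -> int:
        return self.y.shape[0]


@dataclass
class HMMModel:
    """Transition matrix Q, initial distribution, and Gaussian emissions."""

    Q: np.ndarray
    pi: np.ndarray
    mu: np.ndarray  # (n_states, n_dims)
    sigma: np.ndarray  # (n_states, n_dims, n_dims)
    state_labels: list[str]
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def validate(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-12):
            raise ContractError("Q rows must sum to 1")
        if (self.Q < 0).any() or (self.pi < 0).any():
            raise ContractError("Q and pi entries must be >= 0")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ContractError("pi must sum to 1")


@dataclass
class SleepMetrics:
    """Per-night summary: onset latency, total sleep time, stage budget."""

    sleep_onset_latency_min: float | None
    total_sleep_time_h: float
    hours: dict[str, float]
    pct: dict[str, float] | None

    def to_dict(self) -> dict:
        return {
            "sleep_onset_latency_min": self.sleep_onset_latency_min,
            "total_sleep_time_h": self.total_sleep_time_h,
            "hours": self.hours,
            "pct": self.pct,
        }


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_band_features(
    spec: Spectrogram,
    band_set: BandSet | None = None,
    epoch_s: float = 30.0,
) -> EpochFeatures:
    """Average relative dB per scoring band per 30-s epoch.

    Consumes the baselined *unsmoothed* spectrogram (never the line-masked or
    smoothed display versions); the trailing partial epoch is dropped.
    """
    if band_set is None:
        band_set = BandSet()
    if spec.stage_tag != "baselined":
        raise ContractError(
            f"features require the baselined unsmoothed spectrogram, got {spec.stage_tag!r}"
        )
    steps_per_epoch = int(round(epoch_s / spec.step_s))
    n_epochs = int(np.floor(spec.n_steps * spec.step_s / epoch_s))
    if n_epochs < 1:
        raise InsufficientDataError("spectrogram shorter than one epoch")
    band_bins = []
    for name, lo, hi in band_set.bands:
        bins = spec.grid.bins_in_band(lo, hi)
        if bins.size == 0:
            raise ConfigError(f"band {name} [{lo}, {hi}) Hz contains no grid bins")
        band_bins.append(bins)
    y = np.empty((n_epochs, band_set.n_bands))
    for e in range(n_epochs):
        chunk = spec.values_db[e * steps_per_epoch : (e + 1) * steps_per_epoch]
        for k, bins in enumerate(band_bins):
            y[e, k] = chunk[:, bins].mean()
    return EpochFeatures(y=y, epoch_s=epoch_s, band_set=band_set)


# ---------------------------------------------------------------------------
# HMM initialisation
# ---------------------------------------------------------------------------

def init_hmm(features: EpochFeatures, n_states: int = 5) -> HMMModel:
    """Sticky-transition initial model tied to the band identities.

    Q starts at 0.95 on the diagonal and 0.0125 off it; the initial
    distribution is uniform; μ_j seeds from the epochs whose strongest band is
    band j (falling back to the global mean plus a unit offset in column j if
    a band claims no epochs); every Σ_j starts at the global covariance plus a
    small diagonal ridge.
    """
    y = features.y
    n, d = y.shape
    if n < n_states:
        raise InsufficientDataError(f"need >= {n_states} epochs, got {n}")
    Q = np.full((n_states, n_states), Q_INIT_OFFDIAG)
    np.fill_diagonal(Q, Q_INIT_DIAG)
    if n_states != 5:  # the 0.95/0.0125 pair is exact only for 5 states
        Q /= Q.sum(axis=1, keepdims=True)
    pi = np.full(n_states, 1.0 / n_states)
    assign = np.argmax(y, axis=1)
    global_mean = y.mean(axis=0)
    mu = np.empty((n_states, d))
    for j in range(n_states):
        sel = assign == (j % d)
        if sel.any():
            mu[j] = y[sel].mean(axis=0)
        else:
            mu[j] = global_mean
            mu[j, j % d] += 1.0
    cov = np.cov(y, rowvar=False, ddof=0)
    cov = np.atleast_2d(cov)
    ridge = RIDGE_FRACTION * np.trace(cov) / d
    sigma = np.tile(cov + max(ridge, 1e-12) * np.eye(d), (n_states, 1, 1))
    labels = [features.band_set.labels[j % d] for j in range(n_states)]
    return HMMModel(Q=Q, pi=pi, mu=mu, sigma=sigma, state_labels=labels)


# ---------------------------------------------------------------------------
# Gaussian log-densities and forward-backward machinery
# ---------------------------------------------------------------------------

def _log_emissions(model: HMMModel, y: np.ndarray) -> np.ndarray:
    """(T, K) matrix of log N(y_t; μ_j, Σ_j)."""
    T, d = y.shape
    K = model.n_states
    logB = np.empty((T, K))
    for j in range(K):
        sigma = model.sigma[j]
        chol = np.linalg.cholesky(sigma)
        diff = y - model.mu[j]
        z = np.linalg.solve(chol, diff.T)
        maha = (z**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        logB[:, j] = -0.5 * (maha + logdet + d * np.log(2 * np.pi))
    return logB


def _forward_backward(model: HMMModel, logB: np.ndarray):
    """Scaled forward-backward.

    Returns (loglik, gamma, xi_sum) where gamma is the (T, K) posterior state
    matrix and xi_sum the (K, K) expected transition counts.
    """
    T, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise NumericalError("forward pass underflow at t=0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ model.Q) * B[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise NumericalError(f"forward pass underflow at t={t}")
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())

    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (model.Q @ bb) / c[t + 1]
        xi = model.Q * np.outer(alpha[t], bb) / c[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum


def sequence_loglik(model: HMMModel, features: EpochFeatures) -> float:
    """Exact marginal log-likelihood of the epoch sequence (scaled forward)."""
    y = np.atleast_2d(features.y)
    if y.shape[1] != model.mu.shape[1]:
        raise ContractError(
            f"feature dimension {y.shape[1]} != model dimension {model.mu.shape[1]}"
        )
    logB = _log_emissions(model, y)
    loglik, _, _ = _forward_backward(model, logB)
    return loglik


# ---------------------------------------------------------------------------
# EM fitting (Baum-Welch)
# ---------------------------------------------------------------------------

def fit_em(
    model: HMMModel,
    features: EpochFeatures,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    tol: float = DEFAULT_EM_TOL,
) -> HMMModel:
    """Baum-Welch maximum-likelihood fit of Q, π and (μ_j, Σ_j).

    Stops when the relative log-likelihood improvement drops below ``tol`` or
    after ``max_iter`` iterations; each M-step re-adds a small diagonal ridge
    to every covariance so the emissions stay positive-definite even on
    degenerate inputs.  The log-likelihood trace is monotone non-decreasing
    (an EM guarantee) and a decrease beyond float slack raises an error.
    """
    model.validate()
    y = np.atleast_2d(features.y)
    T, d = y.shape
    K = model.n_states
    Q = model.Q.copy()
    pi = model.pi.copy()
    mu = model.mu.copy()
    sigma = model.sigma.copy()
    trace: list[float] = []
    work = HMMModel(Q=Q, pi=pi, mu=mu, sigma=sigma, state_labels=list(model.state_labels))
    for it in range(max_iter):
        logB = _log_emissions(work, y)
        if not np.isfinite(logB).all():
            raise NumericalError(f"non-finite emission log-density at EM iteration {it}")
        loglik, gamma, xi_sum = _forward_backward(work, logB)
        if not np.isfinite(loglik):
            raise NumericalError(f"non-finite log-likelihood at EM iteration {it}")
        if trace:
            delta = loglik - trace[-1]
            # wobble below the convergence tolerance (from covariance
            # re-ridging) terminates; anything larger violates EM
            if abs(delta) < tol * (abs(trace[-1]) + 1e-12):
                if delta >= 0:
                    trace.append(loglik)
                break
            if delta < -(1e-9 + 1e-9 * abs(trace[-1])):
                raise NumericalError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{trace[-1]:.9g} -> {loglik:.9g}"
                )
        trace.append(loglik)
        # M-step
        occ = gamma.sum(axis=0)
        work.pi = gamma[0] / gamma[0].sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        newQ = np.where(denom > 0, xi_sum / np.where(denom > 0, denom, 1.0), work.Q)
        newQ /= newQ.sum(axis=1, keepdims=True)
        work.Q = newQ
        for j in range(K):
            w = gamma[:, j]
            wsum = occ[j]
            if wsum <= 1e-300:
                continue  # starved state: keep previous parameters
            mj = (w[:, None] * y).sum(axis=0) / wsum
            diff = y - mj
            Sj = (w[:, None] * diff).T @ diff / wsum
            ridge = RIDGE_FRACTION * np.trace(Sj) / d
            work.mu[j] = mj
            work.sigma[j] = Sj + max(ridge, 1e-12) * np.eye(d)
    work.loglik_trace = trace
    return work


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def viterbi_decode(model: HMMModel, features: EpochFeatures) -> Hypnogram:
    """Maximum a posteriori state path, mapped to stage labels.

    Log-space dynamic program; ties break toward the lower state index.
    """
    states = viterbi_states(model, features)
    return Hypnogram(
        stages=[model.state_labels[s] for s in states],
        epoch_s=features.epoch_s,
    )


def viterbi_states(model: HMMModel, features: EpochFeatures) -> np.ndarray:
    """Viterbi path as raw state indices (shared by decode and tests)."""
    y = np.atleast_2d(features.y)
    if y.shape[0] == 0:
        raise EmptyInputError("no epochs to decode")
    if y.shape[1] != model.mu.shape[1]:
        raise ContractError("feature/model dimension mismatch")
    logB = _log_emissions(model, y)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logQ = np.log(model.Q)
        logpi = np.log(model.pi)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logQ
        back[t] = np.argmax(cand, axis=0)  # first max → lowest index on ties
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# per-night sleep metrics
# ---------------------------------------------------------------------------

def compute_sleep_metrics(
    h: Hypnogram, min_run_epochs: int = DEFAULT_ONSET_MIN_RUN
) -> SleepMetrics:
    """Onset latency, total sleep time, per-stage hours and percentages.

    Sleep onset is the start of the first run of ``min_run_epochs``
    consecutive non-Wake epochs (default 5 epochs = 2.5 min).  Hours and
    percentages cover all post-onset epochs, Wake included; total sleep time
    counts only post-onset non-Wake epochs.  A night with no qualifying run
    has undefined onset and zero sleep time.
    """
    non_wake = np.array([s != "Wake" for s in h.stages])
    onset_epoch: int | None = None
    run = 0
    for i, nw in enumerate(non_wake):
        run = run + 1 if nw else 0
        if run >= min_run_epochs:
            onset_epoch = i - min_run_epochs + 1
            break
    hours_all = {s: 0.0 for s in STAGES}
    if onset_epoch is None:
        return SleepMetrics(
            sleep_onset_latency_min=None,
            total_sleep_time_h=0.0,
            hours=hours_all,
            pct=None,
        )
    post = h.stages[onset_epoch:]
    epoch_h = h.epoch_s / 3600.0
    for s in post:
        hours_all[s] += epoch_h
    tst = sum(v for k, v in hours_all.items() if k != "Wake")
    pct = {s: 100.0 * hours_all[s] / (len(post) * epoch_h) for s in STAGES}
    return SleepMetrics(
        sleep_onset_latency_min=onset_epoch * h.epoch_s / 60.0,
        total_sleep_time_h=tst,
        hours=hours_all,
        pct=pct,
    )
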