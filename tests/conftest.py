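"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import struct

import numpy as np
import pytest

from somnigram.staging import BandSet, EpochFeatures, HMMModel
from somnigram.staging import _log_emissions  # noqa: the oracle needs densities only
from somnigram.io_formats import STAGES


# ---------------------------------------------------------------------------
# brute-force HMM oracles (path enumeration, independent of the DP code)
# ---------------------------------------------------------------------------

def all_paths(n_states: int, T: int) -> np.ndarray:
    """All state paths in lexicographic order, shape (n_states**T, T)."""
    return np.array(list(itertools.product(range(n_states), repeat=T)), dtype=int)


def path_log_scores(model: HMMModel, y: np.ndarray) -> np.ndarray:
    """Joint log p(path, y) for every possible path, by direct summation."""
    logB = _log_emissions(model, y)
    T, K = logB.shape
    paths = all_paths(K, T)
    with np.errstate(divide="ignore"):
        logQ = np.log(model.Q)
        logpi = np.log(model.pi)
    s = logpi[paths[:, 0]] + logB[np.arange(T)[None, :], paths].sum(axis=1)
    if T > 1:
        s = s + logQ[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return s


def brute_force_viterbi(model: HMMModel, y: np.ndarray) -> np.ndarray:
    scores = path_log_scores(model, y)
    return all_paths(model.n_states, y.shape[0])[int(np.argmax(scores))]


def brute_force_loglik(model: HMMModel, y: np.ndarray) -> float:
    scores = path_log_scores(model, y)
    m = scores.max()
    return float(m + np.log(np.exp(scores - m).sum()))


def random_hmm(rng: np.random.Generator, n_states: int = 5, n_dims: int = 5) -> HMMModel:
    """A random, fully generic HMM (dense transitions, full covariances)."""
    Q = rng.dirichlet(np.ones(n_states), size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    mu = rng.normal(0.0, 2.0, (n_states, n_dims))
    A = rng.normal(0.0, 1.0, (n_states, n_dims, n_dims))
    sigma = np.einsum("kij,klj->kil", A, A) + 0.5 * np.eye(n_dims)
    labels = [STAGES[j % len(STAGES)] for j in range(n_states)]
    return HMMModel(Q=Q, pi=pi, mu=mu, sigma=sigma, state_labels=labels)


def as_features(y: np.ndarray) -> EpochFeatures:
    return EpochFeatures(y=np.atleast_2d(y), epoch_s=30.0, band_set=BandSet())


# ---------------------------------------------------------------------------
# minimal EDF byte builder (header arithmetic only; enough for the reader)
# ---------------------------------------------------------------------------

def build_edf_bytes(
    channels: dict[str, np.ndarray],
    samples_per_record: dict[str, int],
    record_duration_s: float = 1.0,
) -> bytes:
    """Assemble a minimal uncompressed EDF file in memory.

    ``channels`` maps label -> float samples; ``samples_per_record`` gives each
    channel's samples per data record (rate = spr / record_duration).  All
    channels must span the same number of records.
    """
    labels = list(channels)
    ns = len(labels)
    n_records = {
        lab: len(channels[lab]) // samples_per_record[lab] for lab in labels
    }
    assert len(set(n_records.values())) == 1, "channels must cover equal records"
    nrec = next(iter(n_records.values()))

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii").ljust(width)[:width]

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("EDF", 44),
            pad(str(nrec), 8),
            pad(f"{record_duration_s:g}", 8),
            pad(str(ns), 4),
        ]
    )
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    sig = b"".join(pad(lab, 16) for lab in labels)
    sig += b"".join(pad("synthetic", 80) for _ in labels)
    sig += b"".join(pad("uV", 8) for _ in labels)
    sig += b"".join(pad(f"{phys_min:g}", 8) for _ in labels)
    sig += b"".join(pad(f"{phys_max:g}", 8) for _ in labels)
    sig += b"".join(pad(str(dig_min), 8) for _ in labels)
    sig += b"".join(pad(str(dig_max), 8) for _ in labels)
    sig += b"".join(pad("", 80) for _ in labels)
    sig += b"".join(pad(str(samples_per_record[lab]), 8) for lab in labels)
    sig += b"".join(pad("", 32) for _ in labels)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    body = bytearray()
    for r in range(nrec):
        for lab in labels:
            spr = samples_per_record[lab]
            chunk = channels[lab][r * spr : (r + 1) * spr]
            dig = np.clip(
                np.round((chunk - phys_min) * scale + dig_min), dig_min, dig_max
            ).astype("<i2")
            body += struct.pack(f"<{spr}h", *dig)
    return hdr + sig + bytes(body)


@pytest.fixture
def tmp_edf(tmp_path):
    """Factory writing a minimal EDF file and returning its path."""

    def _make(channels, samples_per_record, record_duration_s=1.0, name="test.edf"):
        p = tmp_path / name
        p.write_bytes(build_edf_bytes(channels, samples_per_record, record_duration_s))
        return str(p)

    return _make
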