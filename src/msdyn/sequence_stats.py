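"""Descriptive statistics of microstate label sequences.

Durations, GFP peak rate, the first-order transition model (label distribution
pi and row-stochastic matrix T) and the relaxation time derived from T's
spectral gap.  The transition model is estimated per sample with
self-transitions included — the unsmoothed per-sample convention makes T
strongly diagonal, unlike conventions that collapse runs first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .microstates import MicrostateSequence

__all__ = [
    "TransitionModel",
    "MicrostateStats",
    "mean_durations",
    "transition_model",
    "relaxation_time",
    "summarize_sequence",
]


@dataclass
class TransitionModel:
    """Stationary label distribution pi and K x K row-stochastic matrix T."""

    pi: np.ndarray
    T: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        K = self.pi.size
        if self.T.shape != (K, K):
            raise ValueError("T must be K x K with K = len(pi)")
        if np.any(self.pi < 0) or np.any(self.T < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each row of T must sum to 1")

    @property
    def K(self) -> int:
        return self.pi.size


@dataclass
class MicrostateStats:
    """Per-recording scalar summary of a microstate segmentation."""

    pps: float                      # GFP peaks per second [1/s]
    mmd_ms: float                   # overall mean microstate duration [ms]
    mmd_per_map_ms: np.ndarray      # per-label mean duration [ms]
    gev_total: float
    gev_per_map: np.ndarray
    spectral_gap: float
    relaxation_time: float


def mean_durations(seq: MicrostateSequence) -> tuple[float, np.ndarray]:
    """Mean microstate duration (ms), overall and per label.

    A microstate's duration is the length of a contiguous run of its label
    times the sampling interval.  The first and last runs (possibly truncated
    by the segment boundaries) are included.  Labels that never occur get NaN.
    """
    x = seq.labels
    dt_ms = 1000.0 / seq.fs
    boundaries = np.flatnonzero(np.diff(x) != 0)
    run_ends = np.concatenate([boundaries, [x.size - 1]])
    run_starts = np.concatenate([[0], boundaries + 1])
    run_lengths = run_ends - run_starts + 1
    run_labels = x[run_starts]
    durations = run_lengths * dt_ms
    overall = float(durations.mean())
    per_map = np.full(seq.K, np.nan)
    for k in range(seq.K):
        sel = run_labels == k
        if np.any(sel):
            per_map[k] = float(durations[sel].mean())
    return overall, per_map


def transition_model(seq: MicrostateSequence) -> TransitionModel:
    """Maximum-likelihood (plug-in) transition model from consecutive samples.

    pi holds empirical label frequencies; T_ij is the fraction of i -> j steps
    among all steps leaving i, self-transitions included.  A label with no
    outgoing transitions gets a uniform row (logged warning).
    """
    x = seq.labels
    K = seq.K
    pi = np.bincount(x, minlength=K).astype(float)
    pi /= pi.sum()
    codes = x[:-1] * K + x[1:]
    counts = np.bincount(codes, minlength=K * K).astype(float).reshape(K, K)
    rows = counts.sum(axis=1)
    T = np.empty_like(counts)
    for i in range(K):
        if rows[i] == 0:
            warnings.warn(f"label {i} has no outgoing transitions; using a uniform row")
            T[i] = 1.0 / K
        else:
            T[i] = counts[i] / rows[i]
    return TransitionModel(pi=pi, T=T, n_samples=x.size)


def relaxation_time(model: TransitionModel) -> tuple[float, float]:
    """Spectral gap of T and its inverse, the relaxation time.

    Eigenvalues are ordered by modulus (complex pairs occur for non-reversible
    chains); the gap is 1 - |lambda_2| and governs the geometric rate at which
    the chain forgets its initial condition.  A gap of 0 (e.g. a frozen chain,
    T = identity) reports an infinite relaxation time.
    """
    T = model.T
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8) or np.any(T < 0):
        raise ValueError("T must be row-stochastic")
    evals = np.linalg.eigvals(T)
    mods = np.sort(np.abs(evals))[::-1]
    lam2 = mods[1] if mods.size > 1 else 0.0
    gap = float(1.0 - min(lam2, 1.0))
    trelax = float("inf") if gap == 0 else 1.0 / gap
    return gap, trelax


def summarize_sequence(
    seq: MicrostateSequence,
    pps: float,
    gev_total: float,
    gev_per_map: np.ndarray,
) -> MicrostateStats:
    """Bundle duration, GEV and relaxation statistics into one record."""
    mmd, mmd_per = mean_durations(seq)
    gap, trelax = relaxation_time(transition_model(seq))
    return MicrostateStats(
        pps=pps,
        mmd_ms=mmd,
        mmd_per_map_ms=mmd_per,
        gev_total=gev_total,
        gev_per_map=np.asarray(gev_per_map, dtype=float),
        spectral_gap=gap,
        relaxation_time=trelax,
    )
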