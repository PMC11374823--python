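"""Information-theoretic descriptors of microstate label sequences.

All quantities are plug-in (maximum-likelihood) estimates in bits (log base 2)
and are invariant under relabeling of the microstate classes.  No bias
correction is applied: downstream hypothesis tests compare empirical curves
against Markov surrogates of the same length, which carry the same
finite-sample bias (for an iid K-ary sequence of length n the mutual-
information bias is approximately (K-1)^2 / (2 n ln 2) bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .microstates import MicrostateSequence

__all__ = [
    "AIFCurve",
    "EntropyRateResult",
    "shannon_entropy",
    "entropy_rate",
    "aif",
]


@dataclass
class AIFCurve:
    """Autoinformation function: time-lagged mutual information, in bits.

    ``aif_bits[0]`` equals the sequence's Shannon entropy (mutual information
    of a variable with itself); values are nonnegative by construction.
    """

    lags_ms: np.ndarray
    aif_bits: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.aif_bits = np.asarray(self.aif_bits, dtype=float)
        if self.lags_ms.shape != self.aif_bits.shape:
            raise ValueError("lag grid and values must match")


@dataclass
class EntropyRateResult:
    """Finite entropy rate: H(X_{t+1} | k previous labels), bits per sample."""

    h_bits_per_sample: float
    history_k: int
    window_ms: float


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector; 0*log0 := 0."""
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(x) -> float:
    """Shannon entropy in bits of a label sequence or a probability vector.

    For a sequence the plug-in (empirical frequency) estimate is returned.
    A probability vector must be nonnegative and sum to 1.
    """
    if isinstance(x, MicrostateSequence):
        x = x.labels
    arr = np.asarray(x)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.issubdtype(arr.dtype, np.floating):
        if np.any(arr < 0):
            raise ValueError("negative probabilities")
        if not np.isclose(arr.sum(), 1.0, atol=1e-8):
            raise ValueError("probabilities must sum to 1")
        p = arr[arr > 0]
        return float(-(p * np.log2(p)).sum())
    counts = np.bincount(arr.astype(np.int64))
    return _entropy_from_counts(counts)


def _block_codes(x: np.ndarray, K: int, k: int) -> np.ndarray:
    """Encode overlapping length-k blocks (stride 1) as integers base K."""
    n = x.size - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for p in range(k):
        codes = codes * K + x[p : p + n]
    return codes


def entropy_rate(seq: MicrostateSequence, k: int = 6) -> EntropyRateResult:
    """Finite entropy rate: conditional entropy of the next label given k past.

    Computed as H(blocks of length k+1) - H(blocks of length k) with
    overlapping blocks (stride 1).  The default history of k = 6 samples spans
    24 ms at 250 Hz; for K = 4 labels the estimator needs sequences much
    longer than K^(k+1) samples to be reliable, hence the warning below.
    """
    if k < 1:
        raise ValueError("history length k must be >= 1")
    x = seq.labels
    K = seq.K
    if x.size < 10 * K ** (k + 1):
        warnings.warn(
            f"sequence length {x.size} < 10*K^(k+1) = {10 * K ** (k + 1)}: "
            "entropy-rate estimate is unreliable at this history length"
        )
    h_joint = _entropy_from_counts(np.bincount(_block_codes(x, K, k + 1)))
    h_hist = _entropy_from_counts(np.bincount(_block_codes(x, K, k)))
    return EntropyRateResult(
        h_bits_per_sample=h_joint - h_hist,
        history_k=k,
        window_ms=k * 1000.0 / seq.fs,
    )


def _lagged_mi_bits(x: np.ndarray, K: int, tau: int) -> float:
    """Plug-in mutual information (bits) between X_t and X_{t+tau}."""
    a = x[: x.size - tau]
    b = x[tau:]
    joint = np.bincount(a * K + b, minlength=K * K).astype(float)
    ha = _entropy_from_counts(np.bincount(a, minlength=K))
    hb = _entropy_from_counts(np.bincount(b, minlength=K))
    hab = _entropy_from_counts(joint)
    return max(ha + hb - hab, 0.0)


def aif(seq: MicrostateSequence, max_lag_ms: float = 1000.0) -> AIFCurve:
    """Autoinformation function of a label sequence up to ``max_lag_ms``.

    AIF(tau) = H(X_{t+tau}) - H(X_{t+tau} | X_t), i.e. the mutual information
    between labels tau apart, estimated over all valid pairs.  AIF(0) is the
    plug-in Shannon entropy.  Peaks at regular lags indicate periodically
    recurring microstates, the categorical analogue of ACF oscillations.
    """
    x = seq.labels
    max_lag = int(round(max_lag_ms / 1000.0 * seq.fs))
    if max_lag >= x.size:
        raise ValueError("max lag must be shorter than the sequence")
    vals = np.empty(max_lag + 1)
    vals[0] = shannon_entropy(x)
    for tau in range(1, max_lag + 1):
        vals[tau] = _lagged_mi_bits(x, seq.K, tau)
    lags_ms = np.arange(max_lag + 1) * 1000.0 / seq.fs
    return AIFCurve(lags_ms=lags_ms, aif_bits=vals, n_samples=x.size)
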