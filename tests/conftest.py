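"""Shared fixtures: small recordings, transition models, chain samplers."""

from __future__ import annotations

import numpy as np
import pytest

from msdyn import EEGRecording, TransitionModel, make_topography_basis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng) -> EEGRecording:
    """5-channel, 2 s random average-referenced recording."""
    data = rng.standard_normal((5, 500))
    data -= data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=250.0)


@pytest.fixture
def generic_model() -> TransitionModel:
    """A diagonally dominant, non-reversible 4-state chain."""
    T = np.array(
        [
            [0.70, 0.10, 0.10, 0.10],
            [0.15, 0.60, 0.15, 0.10],
            [0.10, 0.20, 0.60, 0.10],
            [0.05, 0.15, 0.20, 0.60],
        ]
    )
    return TransitionModel(pi=np.full(4, 0.25), T=T)


@pytest.fixture
def basis4():
    return make_topography_basis(30, 4, seed=99)


def second_order_tensor(K: int = 4, eps: float = 0.05) -> np.ndarray:
    """Transition tensor P(c | a, b) with genuine second-order dependence.

    The next label prefers b+1 (mod K) when the label two steps back is even
    and b-1 when it is odd; ``eps`` sets the strength of that preference.
    """
    T2 = np.zeros((K, K, K))
    for a in range(K):
        for b in range(K):
            c_pref = (b + 1) % K if a % 2 == 0 else (b - 1) % K
            row = np.full(K, 1.0 / K)
            row[c_pref] += eps
            row -= eps / K
            T2[a, b] = row / row.sum()
    return T2


def sample_second_order(T2: np.ndarray, length: int, n_chains: int, seed: int) -> np.ndarray:
    """Vectorized sampler for a second-order chain, shape (n_chains, length)."""
    K = T2.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T2.reshape(K * K, K), axis=1)
    out = np.empty((n_chains, length), dtype=np.int64)
    out[:, 0] = rng.integers(0, K, n_chains)
    out[:, 1] = rng.integers(0, K, n_chains)
    s = out[:, 0] * K + out[:, 1]
    for t in range(2, length):
        u = rng.random(n_chains)
        c = (cum[s] < u[:, None]).sum(axis=1)
        out[:, t] = c
        s = (s % K) * K + c
    return out


@pytest.fixture
def second_order_sampler():
    return second_order_tensor, sample_second_order
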