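"""Synthetic multichannel EEG with the statistical structure of vigilance states.

Each vigilance-state recipe plants known ingredients — orthonormal
topographies, an oscillatory regime, 1/f background noise — and returns the
ground truth next to the recording, so every pipeline stage can be verified
against what was planted.

Oscillations are modeled as *rotating fields*: the scalp field moves in the
plane spanned by two orthogonal topographies, ``x(t) m1 + y(t) m2``, where x
and y are independent narrowband Gaussian processes centered on the
oscillation frequency (idealized: ``sin``/``cos``, recovered with bandwidth
0).  Because a narrowband process is anti-correlated with itself half a
period later and microstate fitting ignores polarity, back-fitted labels
recur every ``1/(2f)`` — the frequency-doubling mechanism.  The stochastic
phase/amplitude matters: under a *deterministic* rotation a time shift acts
on the labels as a permutation, which mutual information cannot distinguish
from identity, so the label sequence would look informative at every lag; the
narrowband components decorrelate away from half-period lags and the
autoinformation of the labels then peaks at multiples of ``1/(2f)``, as EEG
does.  A rotating field is confined to a 2-D plane of channel space, so the
state recipes switch the rotation plane through different pairs of the
planted 4-map basis on a ~1 s epoch grid; this spreads the data over all four
maps (making them recoverable by clustering) without touching the
within-epoch periodicity.

State recipes (defaults):

======  =============================================================
W        9.6 Hz pair-rotating field + 1/f noise (alpha regime)
N1       1/f noise only (low-amplitude mixed frequency, no rhythm)
N1_theta 6.6 Hz pair-rotating field + 1/f noise (theta variant)
N2       1/f noise + 12.5 Hz Hann-enveloped spindle bursts (544-1844 ms)
N2_spindle  a single isolated spindle segment (544-1844 ms)
N3       1.1 Hz pair-rotating field, amplitude calibrated so the
         0.5-3 Hz band holds >= 84% of the 0.5-20 Hz first-PC power
======  =============================================================

All outputs are sampled at 250 Hz over 105-210 s (default 158 s), band-limited
to 0.5-20 Hz and average-referenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microstates import MicrostateMaps, MicrostateSequence, _normalize_maps
from .recording import EEGRecording, average_reference
from .sequence_stats import TransitionModel
from .signal_tools import bandpass_filter, first_principal_component, relative_band_power, welch_psd
from .surrogates import markov_surrogate

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_topography_basis",
    "simulate_rotating_field",
    "simulate_state",
    "simulate_label_chain",
]

STATE_FREQS_HZ = {
    "W": 9.6,
    "N1": None,
    "N1_theta": 6.6,
    "N2": 12.5,          # spindle burst carrier
    "N2_spindle": 12.5,
    "N3": 1.1,
}

#: oscillation-to-noise RMS ratios per state.  The first principal component
#: concentrates the spatially coherent oscillation and suppresses incoherent
#: background by ~1/sqrt(n_channels), so these channel-level ratios are far
#: below the resulting first-PC band-power fractions; W = 0.5 puts the
#: first-PC spectral maximum at the alpha peak with ~50% relative alpha power
#: and a total GEV near 0.6
DEFAULT_SNR = {
    "W": 0.5,
    "N1": 0.0,
    "N1_theta": 0.5,
    "N2": 1.5,
    "N2_spindle": 2.0,
    "N3": 1.0,  # starting point; overridden by the delta-power calibration
}

SPINDLE_DURATION_RANGE_S = (0.544, 1.844)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic recording."""

    state: str = "W"
    n_channels: int = 30
    fs: float = 250.0
    duration_s: float | None = None  # per-state default when None
    osc_freq_hz: float | None = None
    snr: float | None = None
    seed: int | None = None
    epoch_s: float = 1.0             # rotation-plane switching scale
    spindle_rate_per_min: float = 6.0
    delta_fraction: float = 0.84     # N3 calibration target
    K: int = 4

    def __post_init__(self) -> None:
        if self.state not in STATE_FREQS_HZ:
            raise ValueError(f"unknown state {self.state!r}; choose from {sorted(STATE_FREQS_HZ)}")
        if self.osc_freq_hz is None:
            self.osc_freq_hz = STATE_FREQS_HZ[self.state]
        if self.snr is None:
            self.snr = DEFAULT_SNR[self.state]
        if self.osc_freq_hz is not None and not self.fs > 2 * self.osc_freq_hz:
            raise ValueError("sampling rate must exceed twice the oscillation frequency")


@dataclass
class GroundTruth:
    """What was planted into a synthetic recording."""

    planted_maps: MicrostateMaps
    planted_label_sequence: MicrostateSequence | None = None
    planted_model: TransitionModel | None = None
    info: dict = field(default_factory=dict)


def make_topography_basis(n_channels: int, K: int = 4, seed: int | None = None) -> MicrostateMaps:
    """K orthonormal, zero-mean channel patterns from low spatial harmonics.

    Channels are laid out on an idealized circular montage; the first few
    sine/cosine harmonics of the montage angle (smooth, dipolar-like patterns)
    are mixed by a seeded random orthogonal transform.  The result is exactly
    orthonormal with zero channel mean — a convenient stand-in for canonical
    microstate topographies.
    """
    if K > n_channels:
        raise ValueError("cannot build more orthogonal maps than channels")
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    n_harm = min(K + 2, n_channels - 1)
    harmonics = []
    order = 1
    while len(harmonics) < n_harm:
        harmonics.append(np.cos(order * theta))
        if len(harmonics) < n_harm:
            harmonics.append(np.sin(order * theta))
        order += 1
    H = np.stack(harmonics)
    H = H - H.mean(axis=1, keepdims=True)
    H /= np.linalg.norm(H, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((H.shape[0], K)))
    maps = Q[:, :K].T @ H
    return MicrostateMaps(maps=_normalize_maps(maps))


def _pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    spatial_sigma_frac: float = 0.1,
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f and smooth topography.

    Independent pink noise per channel is mixed through a Gaussian kernel on
    the circular montage (width ``spatial_sigma_frac`` of the ring), because
    scalp potentials from volume-conducted background activity are spatially
    smooth; without this the background would be unrealistically incoherent
    across channels.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    if spatial_sigma_frac > 0:
        d = np.arange(n_channels)
        d = np.minimum(d, n_channels - d)  # circular channel distance
        kern = np.exp(-0.5 * (d / (spatial_sigma_frac * n_channels)) ** 2)
        S = np.stack([np.roll(kern, i) for i in range(n_channels)])
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        shaped = S @ shaped
    shaped /= np.sqrt(np.mean(shaped**2))
    return shaped


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _narrowband_pair(
    rng: np.random.Generator, n: int, fs: float, freq: float, bandwidth_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent unit-RMS narrowband signals centered on ``freq``.

    Gaussian spectral envelope of standard deviation ``bandwidth_hz / 2``; a
    bandwidth of 0 degenerates to the deterministic quadrature pair
    (sin, cos).
    """
    t = np.arange(n) / fs
    if bandwidth_hz <= 0:
        w = 2 * np.pi * freq * t
        return np.sin(w), np.cos(w)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.exp(-0.5 * ((freqs - freq) / (bandwidth_hz / 2.0)) ** 2)
    weight[0] = 0.0
    out = []
    for _ in range(2):
        spec = np.fft.rfft(rng.standard_normal(n))
        x = np.fft.irfft(spec * weight, n=n)
        out.append(x / max(_rms(x), 1e-30))
    return out[0], out[1]


def simulate_rotating_field(
    spec: SimulationSpec,
    maps: np.ndarray,
    rel_amplitude: tuple[float, float] = (1.0, 0.8),
    bandwidth_hz: float | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Two-map rotating field plus white sensor noise.

    ``data = a1 * map1 * x(t) + a2 * map2 * y(t) + noise`` where (x, y) are
    independent narrowband processes at ``spec.osc_freq_hz`` (idealized
    sin/cos at ``bandwidth_hz = 0``; default bandwidth is f/5, a realistic
    rhythm linewidth) and the noise RMS is set by ``spec.snr``
    (oscillation RMS / noise RMS).  The amplitude asymmetry makes the GFP of
    the deterministic field oscillate at ``2 f`` (two peaks per cycle)
    instead of being constant.  Ground truth records the polarity-ignoring
    recurrence interval ``1/(2 f)``.
    """
    m = np.asarray(maps, dtype=float)
    if m.shape[0] != 2:
        raise ValueError("simulate_rotating_field needs exactly 2 maps")
    m = _normalize_maps(m)
    if abs(float(m[0] @ m[1])) > 1e-6:
        import warnings

        warnings.warn("rotating-field maps are not orthogonal")
    f = spec.osc_freq_hz
    if f is None:
        raise ValueError("spec.osc_freq_hz must be set for a rotating field")
    if bandwidth_hz is None:
        bandwidth_hz = f / 5.0
    duration = spec.duration_s if spec.duration_s is not None else 158.0
    n = int(round(duration * spec.fs))
    rng = np.random.default_rng(spec.seed)
    x, y = _narrowband_pair(rng, n, spec.fs, f, bandwidth_hz)
    a1, a2 = rel_amplitude
    osc = a1 * np.outer(m[0], x) + a2 * np.outer(m[1], y)
    data = osc.copy()
    if spec.snr and spec.snr > 0 and np.isfinite(spec.snr):
        noise = rng.standard_normal(osc.shape)
        noise *= _rms(osc) / (spec.snr * _rms(noise))
        data = data + noise
    rec = EEGRecording(data=data, fs=spec.fs, state_label=spec.state)
    rec = average_reference(rec)
    truth = GroundTruth(
        planted_maps=MicrostateMaps(maps=m),
        info={
            "osc_freq_hz": f,
            "bandwidth_hz": bandwidth_hz,
            "recurrence_interval_ms": 1000.0 / (2 * f),
            "rel_amplitude": list(rel_amplitude),
        },
    )
    return rec, truth


def _pair_schedule(rng: np.random.Generator, K: int, n_epochs: int) -> list[tuple[int, int]]:
    """Random sequence of distinct map pairs, avoiding immediate repeats."""
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    out: list[tuple[int, int]] = []
    prev = -1
    for _ in range(n_epochs):
        idx = int(rng.integers(len(pairs)))
        while idx == prev and len(pairs) > 1:
            idx = int(rng.integers(len(pairs)))
        out.append(pairs[idx])
        prev = idx
    return out


def _pair_rotating_osc(
    rng: np.random.Generator,
    basis: np.ndarray,
    fs: float,
    n_samples: int,
    freq: float,
    epoch_s: float,
    bandwidth_hz: float | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Narrowband rotating field whose rotation plane hops between map pairs.

    The quadrature pair (x, y) is continuous across epochs; only the plane
    changes.  Within an epoch the field is ``m_i x(t) + m_j y(t)``.
    """
    if bandwidth_hz is None:
        bandwidth_hz = freq / 5.0
    x, y = _narrowband_pair(rng, n_samples, fs, freq, bandwidth_hz)
    epoch_len = max(int(round(epoch_s * fs)), 2)
    n_epochs = int(np.ceil(n_samples / epoch_len))
    schedule = _pair_schedule(rng, basis.shape[0], n_epochs)
    osc = np.empty((basis.shape[1], n_samples))
    for e, (i, j) in enumerate(schedule):
        sl = slice(e * epoch_len, min((e + 1) * epoch_len, n_samples))
        osc[:, sl] = np.outer(basis[i], x[sl]) + np.outer(basis[j], y[sl])
    return osc, schedule


def _finalize(data: np.ndarray, spec: SimulationSpec, band: tuple[float, float] = (0.5, 20.0)) -> EEGRecording:
    rec = EEGRecording(data=data, fs=spec.fs, state_label=spec.state)
    rec = bandpass_filter(rec, band[0], band[1], order=6)
    return average_reference(rec)


def _delta_fraction(rec: EEGRecording) -> float:
    pc1 = first_principal_component(rec)
    psd = welch_psd(pc1, rec.fs)
    return relative_band_power(psd, (0.5, 3.0), (0.5, 20.0))


def simulate_state(
    spec: SimulationSpec, basis: MicrostateMaps | None = None
) -> tuple[EEGRecording, GroundTruth]:
    """Generate one synthetic recording following the state's recipe.

    Passing a shared ``basis`` plants the same topographies into several
    recordings (simulated subjects of one group) while noise and oscillation
    realizations stay independent via ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if basis is None:
        basis = make_topography_basis(spec.n_channels, spec.K, seed=int(rng.integers(2**31)))
    elif basis.n_channels != spec.n_channels:
        raise ValueError("basis channel count does not match the spec")
    B = basis.maps
    duration = spec.duration_s
    if duration is None:
        duration = (
            float(rng.uniform(*SPINDLE_DURATION_RANGE_S)) if spec.state == "N2_spindle" else 158.0
        )
    n = int(round(duration * spec.fs))
    info: dict = {"state": spec.state, "duration_s": duration}

    noise = _pink_noise(rng, spec.n_channels, n, spec.fs)

    if spec.state == "N1":
        data = noise
    elif spec.state in ("W", "N1_theta", "N3"):
        osc, schedule = _pair_rotating_osc(rng, B, spec.fs, n, spec.osc_freq_hz, spec.epoch_s)
        info["pair_schedule"] = schedule
        info["osc_freq_hz"] = spec.osc_freq_hz
        info["recurrence_interval_ms"] = 1000.0 / (2 * spec.osc_freq_hz)
        amp = spec.snr * _rms(noise) / _rms(osc)
        if spec.state == "N3":
            # closed-loop calibration: scale the delta oscillation until the
            # 0.5-3 Hz band holds the configured fraction of first-PC power
            lo, hi = amp / 16.0, amp * 16.0
            for _ in range(20):
                mid = np.sqrt(lo * hi)
                frac = _delta_fraction(_finalize(noise + mid * osc, spec))
                if frac < spec.delta_fraction:
                    lo = mid
                else:
                    hi = mid
                if hi / lo < 1.02:
                    break
            amp = hi  # err on the side of more delta
            info["calibrated_snr"] = amp * _rms(osc) / _rms(noise)
        data = noise + amp * osc
    elif spec.state == "N2":
        data = noise.copy()
        bursts = []
        t_next = float(rng.exponential(60.0 / spec.spindle_rate_per_min))
        while t_next < duration:
            dur = float(rng.uniform(*SPINDLE_DURATION_RANGE_S))
            start = int(round(t_next * spec.fs))
            stop = min(start + int(round(dur * spec.fs)), n)
            if stop - start > 4:
                seg = slice(start, stop)
                m = stop - start
                i, j = _pair_schedule(rng, spec.K, 1)[0]
                bx, by = _narrowband_pair(rng, m, spec.fs, spec.osc_freq_hz, spec.osc_freq_hz / 8.0)
                burst = np.outer(B[i], bx) + np.outer(B[j], by)
                burst *= np.hanning(m)[None, :]
                burst *= spec.snr * _rms(noise) / max(_rms(burst), 1e-12)
                data[:, seg] += burst
                bursts.append((start, stop))
            t_next += dur + float(rng.exponential(60.0 / spec.spindle_rate_per_min))
        info["burst_intervals"] = bursts
        info["osc_freq_hz"] = spec.osc_freq_hz
    elif spec.state == "N2_spindle":
        i, j = _pair_schedule(rng, spec.K, 1)[0]
        sx, sy = _narrowband_pair(rng, n, spec.fs, spec.osc_freq_hz, spec.osc_freq_hz / 8.0)
        osc = np.outer(B[i], sx) + np.outer(B[j], sy)
        amp = spec.snr * _rms(noise) / _rms(osc)
        data = noise + amp * osc
        info["osc_freq_hz"] = spec.osc_freq_hz
        info["recurrence_interval_ms"] = 1000.0 / (2 * spec.osc_freq_hz)
    else:  # pragma: no cover - guarded in SimulationSpec
        raise ValueError(f"unknown state {spec.state!r}")

    rec = _finalize(data, spec)
    truth = GroundTruth(planted_maps=basis, info=info)
    return rec, truth


def simulate_label_chain(
    model: TransitionModel, length: int, seed: int | None = None, fs: float = 250.0
) -> MicrostateSequence:
    """Sample a label sequence from a first-order chain (delegates to surrogates)."""
    return markov_surrogate(model, length, seed=seed, fs=fs)
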