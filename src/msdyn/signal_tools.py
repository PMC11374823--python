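"""Continuous-signal utilities: filtering, PCA summary channel, PSD, ACF.

These operate on :class:`~msdyn.recording.EEGRecording` objects or plain 1-D
signals and produce the spectral/autocorrelation curves that the microstate
autoinformation function is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .recording import EEGRecording

__all__ = [
    "PSDCurve",
    "ACFCurve",
    "bandpass_filter",
    "first_principal_component",
    "welch_psd",
    "relative_band_power",
    "acf",
    "local_extrema",
]


@dataclass
class PSDCurve:
    """One-sided power spectral density on a frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # nonnegative densities
    total_area: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be matching 1-D arrays")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power densities must be nonnegative")
        if not self.total_area:
            self.total_area = float(np.trapezoid(self.power, self.freqs))

    def argmax_freq(self) -> float:
        """Frequency of the global PSD maximum."""
        return float(self.freqs[int(np.argmax(self.power))])


@dataclass
class ACFCurve:
    """Normalized autocorrelation on a millisecond lag grid (lag 0 first)."""

    lags_ms: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.lags_ms.shape != self.r.shape or self.lags_ms.ndim != 1:
            raise ValueError("lags_ms and r must be matching 1-D arrays")
        if self.lags_ms[0] != 0:
            raise ValueError("lag grid must start at 0")


def bandpass_filter(
    rec: EEGRecording, low: float = 0.5, high: float = 20.0, order: int = 6
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied forward-backward per channel.

    ``order`` is the design order of the underlying Butterworth filter;
    bidirectional application doubles the effective roll-off and cancels the
    phase response, preserving the timing of topographic events.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low}, {high})"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def first_principal_component(rec: EEGRecording) -> np.ndarray:
    """Project the data onto the leading spatial eigenvector.

    Summarizes the multichannel recording into one signal carrying the largest
    share of channel-space variance.  Channel means are removed before the
    covariance; the eigenvector's largest-magnitude entry is made positive so
    the output sign is deterministic.
    """
    if rec.n_samples <= rec.n_channels:
        raise ValueError("need more samples than channels for a stable PCA")
    X = rec.data - rec.data.mean(axis=1, keepdims=True)
    cov = (X @ X.T) / rec.n_samples
    if np.trace(cov) <= 0:
        raise ValueError("zero-variance recording: PCA undefined")
    evals, evecs = np.linalg.eigh(cov)
    w = evecs[:, -1]
    if w[int(np.argmax(np.abs(w)))] < 0:
        w = -w
    return w @ X


def welch_psd(signal: np.ndarray, fs: float, window_ms: float = 4096.0) -> PSDCurve:
    """Welch PSD estimate with a Hann taper and 50% segment overlap.

    The default 4096 ms window at 250 Hz gives ~0.24 Hz resolution, enough to
    separate the delta/theta/alpha/sigma features of wake and NREM sleep.
    """
    x = np.asarray(signal, dtype=float).ravel()
    nperseg = int(round(window_ms / 1000.0 * fs))
    if nperseg < 2:
        raise ValueError("window too short")
    if x.size < nperseg:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one Welch window ({nperseg})"
        )
    freqs, power = scipy.signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return PSDCurve(freqs=freqs, power=power)


def _band_area(psd: PSDCurve, low: float, high: float) -> float:
    """Trapezoidal area under the PSD over [low, high], interpolating the edges.

    Edge interpolation makes areas exactly additive over adjacent bands.
    """
    f, p = psd.freqs, psd.power
    lo = max(low, f[0])
    hi = min(high, f[-1])
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inner], [hi]))
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def relative_band_power(
    psd: PSDCurve,
    band: tuple[float, float],
    total_band: tuple[float, float] = (0.5, 20.0),
) -> float:
    """Fraction of PSD area in ``band`` relative to ``total_band``.

    Complementary bands partitioning the total band sum to 1 exactly.
    """
    lo, hi = band
    tlo, thi = total_band
    if hi <= lo:
        raise ValueError("empty frequency band")
    if lo < tlo - 1e-12 or hi > thi + 1e-12:
        raise ValueError("band must be contained in total_band")
    total = _band_area(psd, tlo, thi)
    if total <= 0:
        raise ValueError("total band carries no power")
    return _band_area(psd, lo, hi) / total


def acf(signal: np.ndarray, fs: float, max_lag_ms: float = 1000.0) -> ACFCurve:
    """Biased (1/n) normalized autocorrelation of a mean-centered signal.

    The 1/n normalization guarantees a valid correlation sequence
    (|r| <= 1, r(0) = 1).  The lag grid step equals the sampling interval.
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    if max_lag >= n:
        raise ValueError("max lag must be shorter than the signal")
    x = x - x.mean()
    c0 = float(x @ x) / n
    if c0 == 0:
        raise ValueError("zero-variance signal has no autocorrelation")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for tau in range(1, max_lag + 1):
        r[tau] = (x[:-tau] @ x[tau:]) / (n * c0)
    lags_ms = np.arange(max_lag + 1) * 1000.0 / fs
    return ACFCurve(lags_ms=lags_ms, r=r)


def _plateau_extrema(values: np.ndarray) -> tuple[list[int], list[int]]:
    """Strict local minima/maxima indices, plateaus reported at their first index."""
    v = np.asarray(values, dtype=float)
    minima: list[int] = []
    maxima: list[int] = []
    # run-length compress equal-value plateaus
    starts = [0]
    for i in range(1, v.size):
        if v[i] != v[starts[-1]]:
            starts.append(i)
    for j in range(1, len(starts) - 1):
        prev_v = v[starts[j - 1]]
        cur_v = v[starts[j]]
        next_v = v[starts[j + 1]]
        idx = starts[j]
        if prev_v < cur_v > next_v:
            maxima.append(idx)
        elif prev_v > cur_v < next_v:
            minima.append(idx)
    return minima, maxima


def local_extrema(curve) -> tuple[np.ndarray, np.ndarray]:
    """Lags (ms) of strict local minima and maxima of an ACF or AIF curve.

    Three-point criterion (``v[i-1] < v[i] > v[i+1]`` for a maximum, mirrored
    for minima); lag 0 is never reported; a flat plateau is reported at its
    first sample.  Returns ``(minima_lags_ms, maxima_lags_ms)``.
    """
    values = getattr(curve, "r", None)
    if values is None:
        values = getattr(curve, "aif_bits", None)
    if values is None:
        raise TypeError("curve must expose .r (ACF) or .aif_bits (AIF)")
    lags = np.asarray(curve.lags_ms, dtype=float)
    if values.size < 3:
        raise ValueError("curve too short for extremum detection")
    mins, maxs = _plateau_extrema(values)
    mins = [i for i in mins if lags[i] > 0]
    maxs = [i for i in maxs if lags[i] > 0]
    return lags[mins], lags[maxs]
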