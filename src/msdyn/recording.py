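"""Multichannel EEG container and referencing.

The package works on plain ``channels x samples`` voltage matrices (microvolts)
with a declared sampling rate.  All microstate-related quantities downstream
assume average-referenced data, i.e. the mean over channels is zero at every
sample; :func:`average_reference` enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording", "average_reference"]

#: Tolerance (in units of the data's own scale) below which a recording is
#: treated as already average-referenced.
_REF_TOL = 1e-8


@dataclass
class EEGRecording:
    """A multichannel EEG segment.

    Parameters
    ----------
    data
        Voltages, shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel; autogenerated (``ch00`` ...) when omitted.
    state_label
        Optional vigilance-state tag (``W | N1 | N2 | N3 | spindle | unknown``).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("an EEG recording needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def is_average_referenced(self, tol: float = 1e-6) -> bool:
        """True if every sample's channel mean is ~0 relative to signal scale."""
        scale = max(float(np.max(np.abs(self.data))), 1.0)
        return bool(np.max(np.abs(self.data.mean(axis=0))) <= tol * scale)

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        return out


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: subtract the channel mean per sample.

    Idempotent; after the call every column of ``data`` sums to zero within
    floating-point tolerance.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)
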