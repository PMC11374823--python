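"""Readers and writers for recordings, curves, maps, sequences and results.

Plain-text formats throughout: CSV matrices for recordings and maps, JSON for
metadata and test results.  EDF input goes through MNE; EDF output uses a
minimal self-contained 16-bit EDF writer (no installed library exports EDF).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .microstates import MicrostateMaps, MicrostateSequence
from .recording import EEGRecording
from .sequence_stats import TransitionModel

__all__ = [
    "read_edf",
    "write_edf",
    "read_csv_matrix",
    "write_csv_matrix",
    "write_curve_csv",
    "read_curve_csv",
    "write_maps",
    "read_maps",
    "write_sequence",
    "read_sequence",
    "write_transition_json",
    "read_transition_json",
    "write_band_csv",
    "write_json_result",
]


# ---------------------------------------------------------------- recordings

def read_edf(path: str | Path, state_label: str | None = None) -> EEGRecording:
    """Load an EDF file as an EEGRecording (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]), channel_names=list(raw.ch_names),
        state_label=state_label,
    )


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (one data record per second).

    Physical range is taken from the data per channel; amplitudes are
    quantized to 16 bits, so round-trips are exact only to ~1e-4 of the
    channel's peak amplitude.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((rec.n_channels, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data
    nch = rec.n_channels

    def f(x: str, width: int) -> bytes:
        s = x[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("synthetic recording", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (nch + 1)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),
            f(str(nch), 4),
        ]
    )
    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    sig_header = b"".join(
        [f(name, 16) for name in rec.channel_names]
        + [f("", 80)] * nch
        + [f("uV", 8)] * nch
        + [f(f"{phys_min[i]:.6g}", 8) for i in range(nch)]
        + [f(f"{phys_max[i]:.6g}", 8) for i in range(nch)]
        + [f("-32768", 8)] * nch
        + [f("32767", 8)] * nch
        + [f("", 80)] * nch
        + [f(str(spr), 8)] * nch
        + [f("", 32)] * nch
    )
    scale = 65535.0 / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] - 32768.0)
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_csv_matrix(path: str | Path, fs: float | None = None) -> EEGRecording:
    """Read a channels x samples CSV (header row = channel names).

    The sampling rate comes from a ``<name>.json`` sidecar (key ``fs``) when
    present, else from the ``fs`` argument.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    state = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
        state = meta.get("state_label")
    if fs is None:
        raise ValueError("sampling rate not found: provide fs or a JSON sidecar")
    # rows are channels: first column holds channel names
    names = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return EEGRecording(data=data, fs=float(fs), channel_names=names, state_label=state)


def write_csv_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as channels x samples CSV plus a JSON sidecar with fs."""
    path = Path(path)
    df = pd.DataFrame(rec.data)
    df.insert(0, "channel", rec.channel_names)
    df.to_csv(path, index=False)
    meta = {"fs": rec.fs, "state_label": rec.state_label, "n_samples": rec.n_samples}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


# -------------------------------------------------------------------- curves

def write_curve_csv(grid: np.ndarray, values: np.ndarray, path: str | Path,
                    grid_name: str = "grid", value_name: str = "value") -> None:
    """Two-column CSV for PSD/ACF/AIF curves."""
    pd.DataFrame({grid_name: grid, value_name: values}).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_band_csv(ensemble, path: str | Path) -> None:
    """Surrogate AIF band as (lag_ms, lower, mean, upper) CSV."""
    pd.DataFrame(
        {
            "lag_ms": ensemble.lags_ms,
            "lower": ensemble.aif_band_lower,
            "mean": ensemble.aif_mean,
            "upper": ensemble.aif_band_upper,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------- maps

def write_maps(maps: MicrostateMaps, path: str | Path) -> None:
    """Maps as CSV (rows = maps, columns = channels) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(maps.maps).to_csv(path, index=False)
    meta = {
        "labels": maps.labels,
        "gev_total": maps.gev_total,
        "gev_per_map": None if maps.gev_per_map is None else list(maps.gev_per_map),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_maps(path: str | Path) -> MicrostateMaps:
    path = Path(path)
    arr = pd.read_csv(path).to_numpy(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    per = meta.get("gev_per_map")
    return MicrostateMaps(
        maps=arr,
        labels=list(meta.get("labels", [])),
        gev_total=float(meta.get("gev_total", 0.0)),
        gev_per_map=None if per is None else np.asarray(per, float),
    )


# ----------------------------------------------------------------- sequences

def write_sequence(seq: MicrostateSequence, path: str | Path, rle: bool = False) -> None:
    """Label sequence as single-column CSV (or run-length encoded) + JSON header."""
    path = Path(path)
    if rle:
        x = seq.labels
        bounds = np.flatnonzero(np.diff(x) != 0)
        starts = np.concatenate([[0], bounds + 1])
        ends = np.concatenate([bounds, [x.size - 1]])
        pd.DataFrame({"label": x[starts], "length": ends - starts + 1}).to_csv(path, index=False)
    else:
        pd.DataFrame({"label": seq.labels}).to_csv(path, index=False)
    meta = {"fs": seq.fs, "K": seq.K, "n_samples": seq.n_samples, "rle": rle}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_sequence(path: str | Path) -> MicrostateSequence:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    if meta.get("rle"):
        labels = np.repeat(df["label"].to_numpy(np.int64), df["length"].to_numpy(np.int64))
    else:
        labels = df["label"].to_numpy(np.int64)
    return MicrostateSequence(labels=labels, fs=float(meta["fs"]), K=int(meta["K"]))


# -------------------------------------------------------------------- models

def write_transition_json(model: TransitionModel, path: str | Path) -> None:
    payload = {"pi": list(model.pi), "T": model.T.tolist(), "n_samples": model.n_samples}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transition_json(path: str | Path) -> TransitionModel:
    d = json.loads(Path(path).read_text())
    return TransitionModel(pi=np.asarray(d["pi"]), T=np.asarray(d["T"]), n_samples=int(d["n_samples"]))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_result(obj, path: str | Path) -> None:
    """Serialize a result dataclass (or dict) to JSON, arrays as lists."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
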