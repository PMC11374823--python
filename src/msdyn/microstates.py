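"""From multichannel EEG to microstate maps and label sequences.

The segmentation follows the classic polarity-invariant route: global field
power (GFP) peaks supply the clustering input, a modified k-means groups the
peak topographies into K maps using squared spatial correlation (so a map and
its negation are equivalent), group maps are aligned across subjects by a full
label-permutation search, and label sequences are produced by back-fitting the
maps at *every* sample with no temporal smoothing — preserving the sequence's
fast temporal structure, which the information-theoretic analysis depends on.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .recording import EEGRecording, average_reference
from .signal_tools import _plateau_extrema

__all__ = [
    "GFPSeries",
    "MicrostateMaps",
    "MicrostateSequence",
    "gfp",
    "find_gfp_peaks",
    "modified_kmeans",
    "gev",
    "align_group_maps",
    "backfit",
    "assign_canonical_labels",
]


@dataclass
class GFPSeries:
    """Per-sample global field power (spatial standard deviation), in microvolts."""

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values are nonnegative by construction")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def peaks_per_second(self) -> float:
        if self.peak_indices is None:
            raise ValueError("call find_gfp_peaks first")
        return self.peak_indices.size / self.duration_s


@dataclass
class MicrostateMaps:
    """K cluster-centroid topographies: zero channel-mean, unit-norm rows."""

    maps: np.ndarray  # (K, n_channels)
    labels: list[str] = field(default_factory=list)
    gev_total: float = 0.0
    gev_per_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (K, n_channels)")
        if not self.labels:
            self.labels = list(string.ascii_uppercase[: self.K])
        if self.gev_per_map is not None:
            self.gev_per_map = np.asarray(self.gev_per_map, dtype=float)

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class MicrostateSequence:
    """Integer label per EEG sample, at the EEG sampling rate."""

    labels: np.ndarray
    fs: float
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer array")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("labels must lie in {0..K-1}")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.labels.size / self.fs


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero channel-mean and unit Euclidean norm per map (row)."""
    m = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero map encountered during normalization")
    return m / norms


def gfp(rec: EEGRecording) -> GFPSeries:
    """Global field power: spatial standard deviation at each time point.

    GFP(t) = sqrt( (1/N) * sum_i v_i(t)^2 ) for average-referenced potentials
    v_i.  Non-average-referenced input is re-referenced internally (warning).
    """
    if not rec.is_average_referenced():
        warnings.warn("recording is not average-referenced; re-referencing for GFP")
        rec = average_reference(rec)
    values = np.sqrt(np.mean(rec.data**2, axis=0))
    return GFPSeries(values=values, fs=rec.fs)


def find_gfp_peaks(g: GFPSeries) -> np.ndarray:
    """Indices of strict local maxima of the GFP curve.

    Topographies at these instants are treated as momentarily stable fields and
    serve as the clustering input.  Same three-point criterion as
    :func:`~msdyn.signal_tools.local_extrema`; plateaus count once.
    """
    if g.values.size < 3:
        raise ValueError("GFP series too short")
    _, maxima = _plateau_extrema(g.values)
    g.peak_indices = np.asarray(maxima, dtype=np.int64)
    return g.peak_indices


def _spatial_corr(V: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson correlation between each sample topography and each map.

    ``V``: (n_samples, n_channels) topographies, ``maps``: (K, n_channels)
    normalized maps.  Channel means are removed from both sides.  Samples with
    zero spatial variance yield correlation 0 against every map.
    """
    Vc = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Vc, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return (Vc / safe) @ maps.T


def modified_kmeans(
    topographies: np.ndarray,
    K: int = 4,
    n_runs: int = 5,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    ev_trace: list | None = None,
) -> MicrostateMaps:
    """Polarity-invariant (modified) k-means clustering of topographies.

    Assignment maximizes the squared spatial correlation between a sample and a
    centroid, and each centroid is updated as the leading eigenvector of its
    members' outer-product sum — both steps ignore topography polarity.  The
    algorithm is restarted ``n_runs`` times from different seeded
    initializations and the run explaining the most spatial variance wins.

    Returns maps with GEV fields computed on the clustering input (GFP-peak
    topographies), GFP^2-weighted.
    """
    V = np.asarray(topographies, dtype=float)
    if V.ndim != 2:
        raise ValueError("topographies must be (n_samples, n_channels)")
    V = V - V.mean(axis=1, keepdims=True)  # enforce average reference per sample
    norms = np.linalg.norm(V, axis=1)
    V = V[norms > 0]
    if V.shape[0] < K:
        raise ValueError(f"need at least K={K} nonzero topographies, got {V.shape[0]}")
    rng = np.random.default_rng(seed)
    total_sq = float(np.sum(V**2))

    best_ev = -np.inf
    best_maps: np.ndarray | None = None
    best_assign: np.ndarray | None = None
    for _run in range(max(1, n_runs)):
        init_idx = rng.choice(V.shape[0], size=K, replace=False)
        maps = _normalize_maps(V[init_idx])
        prev_ev = -np.inf
        converged = False
        for _it in range(max_iter):
            proj = V @ maps.T  # (n, K)
            assign = np.argmax(proj**2, axis=1)
            fit = proj[np.arange(V.shape[0]), assign]
            ev = float(np.sum(fit**2)) / total_sq
            if ev_trace is not None:
                ev_trace.append((_run, _it, ev))
            # centroid update: leading eigenvector of the members' scatter
            new_maps = maps.copy()
            for k in range(K):
                members = V[assign == k]
                if members.shape[0] == 0:
                    # dead cluster: reseed from the worst-fitted sample
                    worst = int(np.argmin(fit**2))
                    new_maps[k] = V[worst] / np.linalg.norm(V[worst])
                    continue
                S = members.T @ members
                evals, evecs = np.linalg.eigh(S)
                new_maps[k] = evecs[:, -1]
            maps = _normalize_maps(new_maps)
            if ev - prev_ev < tol * max(abs(ev), 1e-12) and _it > 0:
                converged = True
                break
            prev_ev = ev
        if not converged:
            warnings.warn("modified k-means did not converge; returning best iterate")
        if ev > best_ev:
            best_ev, best_maps, best_assign = ev, maps, assign

    assert best_maps is not None and best_assign is not None
    gfp_sq = np.mean(V**2, axis=1)  # GFP(t)^2 of each input topography
    corr = _spatial_corr(V, best_maps)
    fit_corr2 = corr[np.arange(V.shape[0]), best_assign] ** 2
    denom = float(np.sum(gfp_sq))
    per_map = np.array(
        [float(np.sum(gfp_sq[best_assign == k] * fit_corr2[best_assign == k])) / denom for k in range(K)]
    )
    return MicrostateMaps(
        maps=best_maps, gev_total=float(per_map.sum()), gev_per_map=per_map
    )


def gev(
    rec: EEGRecording, maps: MicrostateMaps, seq: MicrostateSequence
) -> tuple[float, np.ndarray]:
    """Global explained variance of the labeled sequence.

    GEV = sum_t GFP(t)^2 corr^2(v_t, map_{label(t)}) / sum_t GFP(t)^2; the
    per-map terms restrict the numerator to samples carrying that label.
    """
    if rec.n_samples != seq.n_samples:
        raise ValueError("recording and sequence lengths differ")
    g = gfp(rec).values
    denom = float(np.sum(g**2))
    if denom == 0:
        raise ValueError("zero total GFP: GEV undefined")
    corr = _spatial_corr(rec.data.T, _normalize_maps(maps.maps))
    fit2 = corr[np.arange(rec.n_samples), seq.labels] ** 2
    num = g**2 * fit2
    per_map = np.array(
        [float(np.sum(num[seq.labels == k])) / denom for k in range(maps.K)]
    )
    return float(per_map.sum()), per_map


def backfit(rec: EEGRecording, maps: MicrostateMaps) -> MicrostateSequence:
    """Assign every sample the map with maximal squared spatial correlation.

    Performed at each time point (not only at GFP peaks) with no smoothing, so
    the sequence keeps the full temporal bandwidth of the field dynamics.  Ties
    break toward the lowest label index; a zero-variance sample inherits the
    previous sample's label (label 0 at the start) with a warning.
    """
    if rec.n_channels != maps.n_channels:
        raise ValueError("channel count of recording and maps differ")
    V = rec.data.T
    corr = _spatial_corr(V, _normalize_maps(maps.maps))
    labels = np.argmax(corr**2, axis=1).astype(np.int64)
    flat = np.linalg.norm(V - V.mean(axis=1, keepdims=True), axis=1) == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance samples: propagating labels")
        idx = np.flatnonzero(flat)
        for i in idx:
            labels[i] = labels[i - 1] if i > 0 else 0
    return MicrostateSequence(labels=labels, fs=rec.fs, K=maps.K)


def _permute_subject(subject: np.ndarray, group: np.ndarray) -> tuple[np.ndarray, float]:
    """Best label permutation of ``subject`` maps against ``group`` maps.

    Maximizes the summed squared correlation; returns (permutation, mean corr^2)
    where ``permutation[k]`` is the subject map index assigned to group slot k.
    """
    corr2 = (group @ subject.T) ** 2  # rows: group slot, cols: subject map
    row, col = linear_sum_assignment(-corr2)
    perm = np.empty(group.shape[0], dtype=int)
    perm[row] = col
    return perm, float(corr2[row, col].mean())


def align_group_maps(
    subject_maps: list[MicrostateMaps],
    n_runs: int = 20,
    seed: int | None = None,
    max_iter: int = 100,
) -> MicrostateMaps:
    """Group maps via a full label-permutation alignment across subjects.

    Each run seeds the group maps with one subject's maps, then alternates
    (i) per-subject optimal label permutation (Hungarian assignment on squared
    correlations, sign-free) and (ii) group-map update as the leading
    eigenvector of the stack of subjects' aligned k-th maps.  The run with the
    maximal mean shared variance (mean squared correlation of subject maps to
    their group map) is returned; ``gev_total``/``gev_per_map`` report that
    shared variance.
    """
    if not subject_maps:
        raise ValueError("need at least one subject")
    K = subject_maps[0].K
    N = subject_maps[0].n_channels
    for m in subject_maps:
        if m.K != K or m.n_channels != N:
            raise ValueError("all subjects must share K and channel count")
    stacks = [_normalize_maps(m.maps) for m in subject_maps]
    if len(stacks) == 1:
        m = subject_maps[0]
        return MicrostateMaps(
            maps=_normalize_maps(m.maps),
            labels=list(m.labels),
            gev_total=1.0,
            gev_per_map=np.ones(K),
        )
    rng = np.random.default_rng(seed)

    best_obj = -np.inf
    best_group: np.ndarray | None = None
    best_per_slot: np.ndarray | None = None
    for _ in range(max(1, n_runs)):
        group = stacks[int(rng.integers(len(stacks)))].copy()
        prev_obj = -np.inf
        for _it in range(max_iter):
            perms = [_permute_subject(s, group) for s in stacks]
            obj = float(np.mean([p[1] for p in perms]))
            new_group = np.empty_like(group)
            per_slot = np.empty(K)
            for k in range(K):
                stack_k = np.stack([s[perm[k]] for s, (perm, _) in zip(stacks, perms)])
                S = stack_k.T @ stack_k
                evals, evecs = np.linalg.eigh(S)
                new_group[k] = evecs[:, -1]
                per_slot[k] = float(np.mean((stack_k @ evecs[:, -1]) ** 2))
            group = _normalize_maps(new_group)
            if obj - prev_obj < 1e-10 and _it > 0:
                break
            prev_obj = obj
        if obj > best_obj:
            best_obj, best_group, best_per_slot = obj, group, per_slot

    assert best_group is not None
    return MicrostateMaps(
        maps=best_group, gev_total=best_obj, gev_per_map=best_per_slot
    )


def canonical_templates(n_channels: int, K: int = 4) -> np.ndarray:
    """Template topographies evoking the canonical A-D geometry.

    Built from low-order harmonics on an idealized circular montage: two
    oblique dipolar axes (A: left-occipital to right-frontal, B: mirrored),
    an occipito-frontal axis (C) and a center-vs-rim pattern (D).  Purely a
    labeling convention; never used in any label-independent metric.
    """
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    cands = [
        np.cos(theta - 3 * np.pi / 4),  # A-like oblique axis
        np.cos(theta + 3 * np.pi / 4),  # B-like mirrored axis
        np.cos(theta),                  # C-like antero-posterior axis
        np.cos(2 * theta),              # D-like radially symmetric-ish
    ]
    while len(cands) < K:
        cands.append(np.sin((len(cands) - 1) * theta))
    return _normalize_maps(np.stack(cands[:K]))


def assign_canonical_labels(
    maps: MicrostateMaps, templates: np.ndarray | None = None
) -> MicrostateMaps:
    """Reorder/label maps A, B, C, ... by maximal |correlation| with templates.

    Cosmetic only: permutes rows and sets letter labels so reports read in the
    conventional order; label-independent metrics are unaffected.
    """
    t = templates if templates is not None else canonical_templates(maps.n_channels, maps.K)
    t = _normalize_maps(np.asarray(t, dtype=float))
    if t.shape != maps.maps.shape:
        raise ValueError("template shape must match maps shape")
    corr2 = (t @ _normalize_maps(maps.maps).T) ** 2
    row, col = linear_sum_assignment(-corr2)
    order = np.empty(maps.K, dtype=int)
    order[row] = col
    per = maps.gev_per_map[order] if maps.gev_per_map is not None else None
    return MicrostateMaps(
        maps=maps.maps[order],
        labels=list(string.ascii_uppercase[: maps.K]),
        gev_total=maps.gev_total,
        gev_per_map=per,
    )
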