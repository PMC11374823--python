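"""End-to-end per-recording and group analysis.

``run_recording`` composes the full chain — band-pass and average reference,
first-PC spectrum and autocorrelation, GFP-peak clustering, back-fitting,
sequence statistics, entropy rate, autoinformation, Markov surrogate band,
the AIF peak test at ACF-derived candidate lags, and Markovianity tests —
into one reproducible report.  Every stochastic stage draws its seed from the
config, so a report is regenerable from (inputs, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import infodynamics, microstates, sequence_stats, signal_tools, surrogates
from .recording import EEGRecording, average_reference

__all__ = ["AnalysisConfig", "AnalysisReport", "GroupReport", "run_recording", "run_group"]

DEFAULT_BANDS = {
    "delta": (0.5, 3.0),
    "theta": (3.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 20.0),
}


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline with their standard defaults."""

    band: tuple[float, float, int] = (0.5, 20.0, 6)  # low Hz, high Hz, order
    K: int = 4
    kmeans_runs: int = 5
    group_runs: int = 20
    max_lag_ms: float = 1000.0
    entropy_k: int = 6
    surrogate_n_band: int = 500
    surrogate_n_peaktest: int = 10
    peak_w_ms: float = 8.0
    alpha: float = 0.05
    welch_window_ms: float = 4096.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    seed: int = 0
    compute_band: bool = True

    def stage_seed(self, stage: str) -> int:
        offsets = {"kmeans": 1, "group": 2, "band": 3, "peaktest": 4}
        return (self.seed * 8191 + offsets[stage]) % (2**31)


@dataclass
class AnalysisReport:
    """Everything computed for one recording."""

    config: AnalysisConfig
    n_samples: int
    fs: float
    state_label: str | None
    psd: signal_tools.PSDCurve
    band_powers: dict
    acf: signal_tools.ACFCurve
    acf_minima_ms: list
    acf_maxima_ms: list
    maps: microstates.MicrostateMaps
    sequence: microstates.MicrostateSequence
    stats: sequence_stats.MicrostateStats
    transition: sequence_stats.TransitionModel
    entropy_bits: float
    entropy_rate: infodynamics.EntropyRateResult
    aif: infodynamics.AIFCurve
    surrogate_band: surrogates.SurrogateEnsemble | None
    peak_test: surrogates.PeakTestResult | None
    peak_test_skipped_reason: str | None
    markov_tests: list


@dataclass
class GroupReport:
    group_maps: microstates.MicrostateMaps
    group_model: sequence_stats.TransitionModel
    reports: list
    metrics: pd.DataFrame
    group_peak_p: float | None = None
    group_peak_significant: bool | None = None


def _candidate_peak_lags(
    acf_curve: signal_tools.ACFCurve,
    minima_ms: np.ndarray,
    maxima_ms: np.ndarray,
    max_lag_ms: float,
    w_ms: float,
    n_samples: int,
) -> list[float]:
    """First two ACF extrema (by lag) usable as AIF peak candidates.

    Only lags whose +/- w window fits inside (0, max_lag] qualify; if the
    second extremum falls outside the analyzed range, only the first is used.
    Extrema whose |r| sits below the large-sample ACF noise level
    ``4 / sqrt(n)`` are estimation wiggles, not oscillatory structure, and are
    skipped.
    """
    floor = 4.0 / np.sqrt(n_samples)
    r_at = dict(zip(acf_curve.lags_ms.tolist(), acf_curve.r.tolist()))
    lags = np.sort(np.concatenate([minima_ms, maxima_ms]))
    usable = [
        float(t)
        for t in lags
        if t - w_ms > 0 and t + w_ms <= max_lag_ms and abs(r_at[float(t)]) >= floor
    ]
    return usable[:2]


def preprocess(rec: EEGRecording, config: AnalysisConfig) -> EEGRecording:
    """Band-pass filter and average-reference a raw recording."""
    low, high, order = config.band
    return average_reference(signal_tools.bandpass_filter(rec, low, high, order))


def run_recording(
    rec: EEGRecording,
    config: AnalysisConfig | None = None,
    maps: microstates.MicrostateMaps | None = None,
    preprocessed: bool = False,
    bonferroni_m: int = 1,
) -> AnalysisReport:
    """Full analysis of one recording.

    When ``maps`` is given (e.g. group maps), clustering is skipped and the
    provided maps are back-fitted instead.
    """
    config = config or AnalysisConfig()
    if not preprocessed:
        rec = preprocess(rec, config)

    # spectrum and autocorrelation of the one-channel PCA summary
    pc1 = signal_tools.first_principal_component(rec)
    psd = signal_tools.welch_psd(pc1, rec.fs, config.welch_window_ms)
    low, high, _ = config.band
    band_powers = {
        name: signal_tools.relative_band_power(psd, b, (low, high))
        for name, b in config.bands.items()
    }
    acf_curve = signal_tools.acf(pc1, rec.fs, config.max_lag_ms)
    acf_min, acf_max = signal_tools.local_extrema(acf_curve)

    # segmentation
    g = microstates.gfp(rec)
    peaks = microstates.find_gfp_peaks(g)
    if maps is None:
        maps = microstates.modified_kmeans(
            rec.data.T[peaks],
            K=config.K,
            n_runs=config.kmeans_runs,
            seed=config.stage_seed("kmeans"),
        )
    seq = microstates.backfit(rec, maps)
    gev_total, gev_per_map = microstates.gev(rec, maps, seq)

    stats = sequence_stats.summarize_sequence(seq, g.peaks_per_second, gev_total, gev_per_map)
    model = sequence_stats.transition_model(seq)

    # information dynamics
    entropy_bits = infodynamics.shannon_entropy(seq)
    h_rate = infodynamics.entropy_rate(seq, config.entropy_k)
    aif_curve = infodynamics.aif(seq, config.max_lag_ms)

    band = None
    if config.compute_band:
        band = surrogates.aif_confidence_band(
            model,
            seq.n_samples,
            config.max_lag_ms,
            n=config.surrogate_n_band,
            alpha=config.alpha,
            seed=config.stage_seed("band"),
            fs=seq.fs,
        )

    taus = _candidate_peak_lags(
        acf_curve, acf_min, acf_max, config.max_lag_ms, config.peak_w_ms, rec.n_samples
    )
    peak_test = None
    skipped = None
    if taus:
        peak_test = surrogates.aif_peak_test(
            seq,
            taus,
            w_ms=config.peak_w_ms,
            n_surrogates=config.surrogate_n_peaktest,
            max_lag_ms=config.max_lag_ms,
            alpha=config.alpha,
            seed=config.stage_seed("peaktest"),
        )
    else:
        skipped = "no ACF extrema found in the analyzed lag range"

    mtests = [
        surrogates.markov_test(seq, order, alpha=config.alpha, bonferroni_m=bonferroni_m)
        for order in (0, 1, 2)
    ]

    return AnalysisReport(
        config=config,
        n_samples=rec.n_samples,
        fs=rec.fs,
        state_label=rec.state_label,
        psd=psd,
        band_powers=band_powers,
        acf=acf_curve,
        acf_minima_ms=list(acf_min),
        acf_maxima_ms=list(acf_max),
        maps=maps,
        sequence=seq,
        stats=stats,
        transition=model,
        entropy_bits=entropy_bits,
        entropy_rate=h_rate,
        aif=aif_curve,
        surrogate_band=band,
        peak_test=peak_test,
        peak_test_skipped_reason=skipped,
        markov_tests=mtests,
    )


def average_models(models: list[sequence_stats.TransitionModel]) -> sequence_stats.TransitionModel:
    """Group (pi, T): average entries across recordings, then renormalize."""
    pi = np.mean([m.pi for m in models], axis=0)
    pi = pi / pi.sum()
    T = np.mean([m.T for m in models], axis=0)
    T = T / T.sum(axis=1, keepdims=True)
    return sequence_stats.TransitionModel(pi=pi, T=T, n_samples=int(np.sum([m.n_samples for m in models])))


def metrics_table(reports: list[AnalysisReport]) -> pd.DataFrame:
    """Tidy one-row-per-recording table for downstream group statistics."""
    rows = []
    for i, r in enumerate(reports):
        row = {
            "recording": i,
            "state": r.state_label,
            "n_samples": r.n_samples,
            "pps": r.stats.pps,
            "mmd_ms": r.stats.mmd_ms,
            "gev_total": r.stats.gev_total,
            "spectral_gap": r.stats.spectral_gap,
            "relaxation_time": r.stats.relaxation_time,
            "entropy_bits": r.entropy_bits,
            "entropy_rate_bits": r.entropy_rate.h_bits_per_sample,
        }
        for k in range(r.maps.K):
            row[f"mmd_{r.maps.labels[k]}_ms"] = r.stats.mmd_per_map_ms[k]
            row[f"gev_{r.maps.labels[k]}"] = r.stats.gev_per_map[k]
        for name, val in r.band_powers.items():
            row[f"relpower_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def run_group(recs: list[EEGRecording], config: AnalysisConfig | None = None) -> GroupReport:
    """Group analysis: shared maps, per-recording back-fit, pooled null model.

    Subject maps are clustered per recording, aligned into group maps by the
    full-permutation procedure, and the group maps are back-fitted into every
    recording.  The surrogate null pools (pi, T) across recordings.  The
    group-level AIF peak test compares per-recording empirical peak statistics
    against pooled surrogate statistics with a one-sided rank-sum test.
    """
    config = config or AnalysisConfig()
    if not recs:
        raise ValueError("need at least one recording")
    n_ch = recs[0].n_channels
    if any(r.n_channels != n_ch for r in recs):
        raise ValueError("all recordings must share the montage")
    pre = [preprocess(r, config) for r in recs]
    subject_maps = []
    for i, r in enumerate(pre):
        g = microstates.gfp(r)
        peaks = microstates.find_gfp_peaks(g)
        subject_maps.append(
            microstates.modified_kmeans(
                r.data.T[peaks], K=config.K, n_runs=config.kmeans_runs,
                seed=config.stage_seed("kmeans") + i,
            )
        )
    if len(pre) == 1:
        group_maps = subject_maps[0]
    else:
        group_maps = microstates.align_group_maps(
            subject_maps, n_runs=config.group_runs, seed=config.stage_seed("group")
        )
    reports = [
        run_recording(
            r, replace(config, seed=config.seed + i), maps=group_maps,
            preprocessed=True, bonferroni_m=len(pre),
        )
        for i, r in enumerate(pre)
    ]
    group_model = average_models([r.transition for r in reports])

    group_p = None
    group_sig = None
    emp_stats = [r.peak_test.statistic_empirical for r in reports if r.peak_test is not None]
    surr_stats = [s for r in reports if r.peak_test is not None for s in r.peak_test.statistics_surrogate]
    if emp_stats and surr_stats:
        group_p, group_sig = surrogates.aif_peak_test_group(emp_stats, surr_stats, config.alpha)

    return GroupReport(
        group_maps=group_maps,
        group_model=group_model,
        reports=reports,
        metrics=metrics_table(reports),
        group_peak_p=group_p,
        group_peak_significant=group_sig,
    )
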