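"""Markov null models and hypothesis tests for microstate sequences.

The null model throughout is the first-order Markov chain fitted to the
empirical sequence (label distribution pi, transition matrix T).  Surrogates
sampled from that chain carry the same single-step statistics and the same
plug-in estimation bias as the data, so differences in the autoinformation
function (AIF) isolate genuinely non-Markovian structure such as oscillatory
recurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .infodynamics import AIFCurve, aif
from .microstates import MicrostateSequence
from .sequence_stats import TransitionModel, transition_model

__all__ = [
    "SurrogateEnsemble",
    "PeakTestResult",
    "MarkovTestResult",
    "markov_surrogate",
    "markov_surrogate_batch",
    "aif_confidence_band",
    "aif_peak_test",
    "aif_peak_test_group",
    "markov_test",
    "significant_aif_peaks",
]


@dataclass
class SurrogateEnsemble:
    """Pointwise AIF confidence band from an ensemble of Markov surrogates."""

    source_model: TransitionModel
    n_surrogates: int
    length: int
    seed: int | None
    lags_ms: np.ndarray
    aif_band_lower: np.ndarray
    aif_band_upper: np.ndarray
    aif_mean: np.ndarray
    alpha: float = 0.05


@dataclass
class PeakTestResult:
    """Outcome of the AIF peak test at candidate lags tau_k."""

    peak_lags_ms: list[float]
    window_halfwidth_ms: float
    statistic_empirical: float
    statistics_surrogate: list[float] = field(default_factory=list)
    p_value: float = 1.0
    significant: bool = False
    alpha: float = 0.05


@dataclass
class MarkovTestResult:
    """Likelihood-ratio (G) test of a Markov property of order 0, 1 or 2."""

    order: int
    statistic: float
    dof: int
    p_value: float
    alpha: float
    bonferroni_m: int
    rejected: bool


def _sample_initial(cum_pi: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cum_pi, u, side="right"))


def markov_surrogate(
    model: TransitionModel, length: int, seed: int | None = None, fs: float = 250.0
) -> MicrostateSequence:
    """Sample one sequence from the first-order chain (pi, T).

    X_0 ~ pi, X_{t+1} ~ T[X_t].  Reproducible: the same (model, length, seed)
    gives the identical sequence.
    """
    if length < 2:
        raise ValueError("surrogate length must be at least 2")
    rng = np.random.default_rng(seed)
    u = rng.random(length)
    K = model.K
    cum_pi = np.cumsum(model.pi)
    # row-wise cumulative transition probabilities as plain lists: the scalar
    # sampling loop below is the hot path and python-list indexing beats numpy
    # scalar indexing by a wide margin
    cum_rows = [list(np.cumsum(model.T[i])[:-1]) for i in range(K)]
    out = np.empty(length, dtype=np.int64)
    x = _sample_initial(cum_pi, u[0])
    out[0] = x
    uu = u.tolist()
    for t in range(1, length):
        row = cum_rows[x]
        v = uu[t]
        j = 0
        for edge in row:
            if v < edge:
                break
            j += 1
        x = j
        out[t] = x
    return MicrostateSequence(labels=out, fs=fs, K=K)


def markov_surrogate_batch(
    model: TransitionModel,
    length: int,
    n_chains: int,
    seed: int | None = None,
) -> np.ndarray:
    """Sample ``n_chains`` independent chains at once, shape (n_chains, length).

    Vectorized over chains (one numpy step per time point), which is the fast
    path for confidence bands and test-calibration ensembles.
    """
    if length < 2:
        raise ValueError("surrogate length must be at least 2")
    rng = np.random.default_rng(seed)
    cum_pi = np.cumsum(model.pi)
    cum_T = np.cumsum(model.T, axis=1)
    out = np.empty((n_chains, length), dtype=np.int64)
    state = np.searchsorted(cum_pi, rng.random(n_chains), side="right")
    out[:, 0] = state
    for t in range(1, length):
        u = rng.random(n_chains)
        state = (cum_T[state] < u[:, None]).sum(axis=1)
        out[:, t] = state
    return out


def aif_confidence_band(
    model: TransitionModel,
    length: int,
    max_lag_ms: float = 1000.0,
    n: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    fs: float = 250.0,
) -> SurrogateEnsemble:
    """Pointwise (alpha/2, 1-alpha/2) AIF percentile band under the Markov null.

    Each of the ``n`` surrogates has the requested length, so the band absorbs
    the length-dependent plug-in bias of the AIF estimator.
    """
    if n < 2:
        raise ValueError("need at least 2 surrogates for a band")
    chains = markov_surrogate_batch(model, length, n, seed=seed)
    curves = np.stack(
        [
            aif(MicrostateSequence(labels=c, fs=fs, K=model.K), max_lag_ms).aif_bits
            for c in chains
        ]
    )
    lags_ms = np.arange(curves.shape[1]) * 1000.0 / fs
    lower = np.quantile(curves, alpha / 2, axis=0)
    upper = np.quantile(curves, 1 - alpha / 2, axis=0)
    return SurrogateEnsemble(
        source_model=model,
        n_surrogates=n,
        length=length,
        seed=seed,
        lags_ms=lags_ms,
        aif_band_lower=lower,
        aif_band_upper=upper,
        aif_mean=curves.mean(axis=0),
        alpha=alpha,
    )


def significant_aif_peaks(curve: AIFCurve, ensemble: SurrogateEnsemble) -> np.ndarray:
    """Lags (ms) of strict AIF local maxima exceeding the surrogate band.

    The plug-in AIF fluctuates at its finite-sample bias floor, so raw strict
    maxima include noise wiggles there; peaks are therefore read off, as in
    the confidence-interval comparison, only where the curve exceeds the
    upper band of the Markov ensemble.
    """
    from .signal_tools import local_extrema

    if curve.aif_bits.size != ensemble.aif_band_upper.size:
        raise ValueError("curve and ensemble must share the lag grid")
    _, maxima = local_extrema(curve)
    above = {
        float(lag)
        for lag, v, u in zip(curve.lags_ms, curve.aif_bits, ensemble.aif_band_upper)
        if v > u
    }
    return np.asarray([lag for lag in maxima if float(lag) in above])


def _peak_statistic(
    curve: AIFCurve, peak_lags_ms: list[float], w_ms: float, max_lag_ms: float
) -> tuple[float, list[float]]:
    """Normalized AIF area in windows around the candidate lags.

    Returns ``(S, per_peak)`` where per_peak[k] is the trapezoidal AUC of the
    AIF over [tau_k - w, tau_k + w] divided by the AUC over (0, max_lag], and
    S is their sum.  Lag 0 is excluded from the normalization: AIF(0) is the
    Shannon entropy and would dominate the area.
    """
    lags = curve.lags_ms
    vals = curve.aif_bits
    pos = lags > 0
    A = float(np.trapezoid(vals[pos], lags[pos]))
    if A <= 0:
        return 0.0, [0.0] * len(peak_lags_ms)
    per_peak = []
    for tau in peak_lags_ms:
        if not (0 < tau - w_ms) or tau + w_ms > max_lag_ms:
            raise ValueError(
                f"window around tau={tau} ms exceeds the analyzed lag range"
            )
        sel = pos & (lags >= tau - w_ms) & (lags <= tau + w_ms)
        if sel.sum() < 2:
            raise ValueError(f"window around tau={tau} ms covers fewer than 2 lags")
        per_peak.append(float(np.trapezoid(vals[sel], lags[sel])) / A)
    return float(sum(per_peak)), per_peak


def aif_peak_test(
    seq: MicrostateSequence,
    peak_lags_ms: list[float],
    w_ms: float = 8.0,
    n_surrogates: int = 10,
    max_lag_ms: float = 1000.0,
    alpha: float = 0.05,
    seed: int | None = None,
    model: TransitionModel | None = None,
) -> PeakTestResult:
    """Test whether the AIF has significant peaks at the candidate lags.

    The per-peak normalized windowed AIF areas of the empirical sequence are
    compared, one-sided, against the pooled per-peak areas of Markov
    surrogates fitted to the sequence's own (pi, T) unless ``model`` is
    supplied, with an exact Mann-Whitney U test (m empirical values against
    n*m surrogate values).  For a single candidate lag this degenerates to the
    exact rank p-value p = (1 + #{S_surr >= S_emp}) / (n + 1).
    ``statistic_empirical`` and ``statistics_surrogate`` report the summed
    normalized areas.
    """
    emp_aif = aif(seq, max_lag_ms)
    s_emp, emp_per_peak = _peak_statistic(emp_aif, peak_lags_ms, w_ms, max_lag_ms)
    if model is None:
        model = transition_model(seq)
    chains = markov_surrogate_batch(model, seq.n_samples, n_surrogates, seed=seed)
    s_surr = []
    surr_per_peak: list[float] = []
    for c in chains:
        tot, per = _peak_statistic(
            aif(MicrostateSequence(labels=c, fs=seq.fs, K=model.K), max_lag_ms),
            peak_lags_ms,
            w_ms,
            max_lag_ms,
        )
        s_surr.append(tot)
        surr_per_peak.extend(per)
    if len(peak_lags_ms) == 1:
        p = (1 + sum(1 for s in s_surr if s >= s_emp)) / (n_surrogates + 1)
    else:
        p = float(
            sps.mannwhitneyu(
                emp_per_peak, surr_per_peak, alternative="greater", method="exact"
            ).pvalue
        )
    return PeakTestResult(
        peak_lags_ms=[float(t) for t in peak_lags_ms],
        window_halfwidth_ms=w_ms,
        statistic_empirical=s_emp,
        statistics_surrogate=[float(s) for s in s_surr],
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def aif_peak_test_group(
    empirical_stats: list[float],
    surrogate_stats: list[float],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Group-level peak test: one-sided Mann-Whitney U.

    Compares per-subject empirical peak statistics against pooled surrogate
    statistics; the alternative is that empirical values are larger.
    """
    u = sps.mannwhitneyu(empirical_stats, surrogate_stats, alternative="greater")
    return float(u.pvalue), bool(u.pvalue < alpha)


def _g_statistic(counts: np.ndarray, axes_shape: tuple[int, ...]) -> float:
    """Conditional-independence G statistic from a contingency tensor.

    ``counts`` has shape (cond..., a, b) flattened as given by ``axes_shape``:
    the last two axes are the variables tested for independence, conditioned on
    all leading axes.  Zero cells contribute zero.
    """
    c = counts.reshape(axes_shape).astype(float)
    n_ab = c  # joint given condition
    n_a = c.sum(axis=-1, keepdims=True)
    n_b = c.sum(axis=-2, keepdims=True)
    n_tot = c.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = n_ab * n_tot / (n_a * n_b)
        terms = np.where(n_ab > 0, n_ab * np.log(np.where(n_ab > 0, ratio, 1.0)), 0.0)
    return float(2.0 * terms.sum())


def markov_test(
    seq: MicrostateSequence,
    order: int,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> MarkovTestResult:
    """Likelihood-ratio test of the Markov property of the given order.

    order 0: X_{t+1} independent of X_t                      (dof (K-1)^2)
    order 1: X_{t+1} independent of X_{t-1} given X_t        (dof K(K-1)^2)
    order 2: X_{t+1} independent of X_{t-2} given X_{t-1},X_t (dof K^2(K-1)^2)

    Counts come from contiguous label tuples; p-values use the chi-square
    asymptotics of the G statistic; the null is rejected at alpha / m with the
    Bonferroni factor ``m``.  A warning is raised when most expected cell
    counts fall below 5 (short sequences: the test loses power, see the
    sleep-spindle-length behaviour exercised in the tests).
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    x = seq.labels
    K = seq.K
    m = order + 2  # tuple length
    if x.size < m + 1:
        raise ValueError("sequence too short for this order")
    codes = np.zeros(x.size - m + 1, dtype=np.int64)
    for p in range(m):
        codes = codes * K + x[p : p + codes.size]
    counts = np.bincount(codes, minlength=K**m).astype(float)

    n_tuples = counts.sum()
    if n_tuples / K**m < 5 and np.mean(counts >= 5) < 0.5:
        warnings.warn(
            f"order-{order} test: most expected cell counts are below 5; "
            "chi-square asymptotics and test power are unreliable"
        )

    if order == 0:
        shape = (K, K)
        dof = (K - 1) ** 2
        g = _g_statistic(counts, shape)
    elif order == 1:
        # (a, b, c) = (X_{t-1}, X_t, X_{t+1}); condition on the middle label:
        # reorder so the conditioning axis leads
        c3 = counts.reshape(K, K, K).transpose(1, 0, 2)
        dof = K * (K - 1) ** 2
        g = _g_statistic(c3, (K, K, K))
    else:
        # (a, b, c, d) = (X_{t-2}, X_{t-1}, X_t, X_{t+1}); condition on (b, c)
        c4 = counts.reshape(K, K, K, K).transpose(1, 2, 0, 3)
        dof = K**2 * (K - 1) ** 2
        g = _g_statistic(c4, (K, K, K, K))

    p = float(sps.chi2.sf(g, dof))
    return MarkovTestResult(
        order=order,
        statistic=g,
        dof=dof,
        p_value=p,
        alpha=alpha,
        bonferroni_m=bonferroni_m,
        rejected=bool(p < alpha / bonferroni_m),
    )
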