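"""Markov surrogates, AIF confidence bands, the AIF peak test, Markov tests."""

import numpy as np
import pytest

from msdyn import (
    AIFCurve,
    MicrostateSequence,
    TransitionModel,
    aif,
    aif_confidence_band,
    aif_peak_test,
    aif_peak_test_group,
    markov_surrogate,
    markov_surrogate_batch,
    markov_test,
    significant_aif_peaks,
    transition_model,
)
from msdyn.surrogates import _peak_statistic
from msdyn.synthetic import _narrowband_pair

FS = 250.0


def _periodic_labels(n, seed, freq=12.5, fs=FS):
    """Labels from the polarity-folded phase of a narrowband rotation.

    The phase angle (mod pi) of a narrowband quadrature pair at ``freq`` is
    quantized into 4 sectors: a stochastic periodic sequence whose
    autoinformation peaks at multiples of the half period (40 ms at 12.5 Hz).
    """
    rng = np.random.default_rng(seed)
    x, y = _narrowband_pair(rng, n, fs, freq, freq / 5.0)
    ang = np.arctan2(y, x) % np.pi
    labels = np.minimum((ang / (np.pi / 4)).astype(np.int64), 3)
    return MicrostateSequence(labels=labels, fs=fs, K=4)


class TestMarkovSurrogate:
    def test_frozen_chain_constant_output(self):
        model = TransitionModel(pi=np.array([0.0, 1.0, 0.0, 0.0]), T=np.eye(4))
        seq = markov_surrogate(model, 500, seed=0)
        assert np.all(seq.labels == 1)

    def test_cyclic_chain_deterministic_cycle(self):
        T = np.roll(np.eye(4), 1, axis=1)
        model = TransitionModel(pi=np.full(4, 0.25), T=T)
        seq = markov_surrogate(model, 100, seed=1)
        diffs = (np.diff(seq.labels) - 1) % 4
        assert np.all(diffs == 0)

    def test_consistency_with_source_model(self, generic_model):
        seq = markov_surrogate(generic_model, 10**5, seed=2)
        est = transition_model(seq)
        assert np.abs(est.T - generic_model.T).max() < 0.03

    def test_reproducible_given_seed(self, generic_model):
        a = markov_surrogate(generic_model, 5000, seed=33)
        b = markov_surrogate(generic_model, 5000, seed=33)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_batch_matches_marginals(self, generic_model):
        chains = markov_surrogate_batch(generic_model, 2000, 50, seed=4)
        assert chains.shape == (50, 2000)
        pooled = MicrostateSequence(labels=chains.ravel(), fs=FS, K=4)
        # pooled label frequencies approach the stationary distribution
        T = generic_model.T
        evals, evecs = np.linalg.eig(T.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi /= pi.sum()
        freqs = np.bincount(pooled.labels, minlength=4) / pooled.n_samples
        assert np.abs(freqs - pi).max() < 0.01

    def test_too_short_errors(self, generic_model):
        with pytest.raises(ValueError):
            markov_surrogate(generic_model, 1, seed=0)


class TestConfidenceBand:
    def test_band_ordering_and_regeneration(self, generic_model):
        band = aif_confidence_band(generic_model, 3000, 200.0, n=50, seed=5)
        assert np.all(band.aif_band_lower <= band.aif_mean + 1e-12)
        assert np.all(band.aif_mean <= band.aif_band_upper + 1e-12)
        again = aif_confidence_band(generic_model, 3000, 200.0, n=50, seed=5)
        np.testing.assert_array_equal(band.aif_band_upper, again.aif_band_upper)

    def test_memoryless_band_collapses_to_bias_floor(self):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        model = TransitionModel(pi=pi, T=np.tile(pi, (4, 1)))
        n_samp = 20000
        band = aif_confidence_band(model, n_samp, 200.0, n=50, seed=6)
        bias = 9 / (2 * n_samp * np.log(2))
        assert band.aif_mean[1:].max() < 10 * bias
        # the mean surrogate AIF is flat: no peaks above noise
        assert band.aif_mean[1:].std() < bias

    def test_coverage_of_matched_surrogates(self, generic_model):
        band = aif_confidence_band(generic_model, 4000, 200.0, n=200, seed=7)
        fractions = []
        for i in range(20):
            seq = markov_surrogate(generic_model, 4000, seed=1000 + i)
            curve = aif(seq, 200.0).aif_bits
            inside = (curve >= band.aif_band_lower) & (curve <= band.aif_band_upper)
            fractions.append(inside[1:].mean())
        assert 0.90 <= np.mean(fractions) <= 1.0

    def test_band_narrows_with_length(self, generic_model):
        short = aif_confidence_band(generic_model, 3000, 100.0, n=60, seed=8)
        long = aif_confidence_band(generic_model, 30000, 100.0, n=60, seed=8)
        w_short = (short.aif_band_upper - short.aif_band_lower)[1:].mean()
        w_long = (long.aif_band_upper - long.aif_band_lower)[1:].mean()
        assert w_long < w_short / 2

    def test_too_few_surrogates_errors(self, generic_model):
        with pytest.raises(ValueError):
            aif_confidence_band(generic_model, 1000, 100.0, n=1)


class TestPeakStatistic:
    def test_flat_curve_analytic_value(self):
        lags = np.arange(251) * 4.0  # 0..1000 ms
        curve = AIFCurve(lags_ms=lags, aif_bits=np.full(251, 0.3), n_samples=1000)
        total, per = _peak_statistic(curve, [100.0, 500.0], 8.0, 1000.0)
        # each window spans 16 ms of a flat curve; total area spans 4..1000 ms
        expected_each = 16.0 / 996.0
        np.testing.assert_allclose(per, expected_each, rtol=1e-12)
        assert abs(total - 2 * expected_each) < 1e-12
        assert total <= 1.0

    def test_window_outside_range_errors(self):
        lags = np.arange(26) * 4.0
        curve = AIFCurve(lags_ms=lags, aif_bits=np.ones(26), n_samples=100)
        with pytest.raises(ValueError):
            _peak_statistic(curve, [100.0], 8.0, 100.0)


class TestAIFPeakTest:
    def test_periodic_sequence_beats_every_surrogate(self):
        # stochastic periodic labels: AIF peaks at 40/80 ms that first-order
        # surrogates cannot reproduce
        seq = _periodic_labels(4000, seed=9)
        res = aif_peak_test(seq, [40.0, 80.0], seed=90)
        assert res.statistic_empirical > max(res.statistics_surrogate)
        assert res.significant and res.p_value < 0.05

    def test_markov_input_not_significant_typically(self, generic_model):
        seq = markov_surrogate(generic_model, 3000, seed=10)
        res = aif_peak_test(seq, [50.0, 100.0], seed=11)
        assert 0.0 < res.p_value <= 1.0
        assert res.statistic_empirical <= 1.0

    def test_reproducibility(self, generic_model):
        seq = markov_surrogate(generic_model, 3000, seed=12)
        a = aif_peak_test(seq, [50.0, 100.0], seed=13)
        b = aif_peak_test(seq, [50.0, 100.0], seed=13)
        assert a.p_value == b.p_value
        assert a.statistics_surrogate == b.statistics_surrogate

    def test_single_peak_uses_rank_formula(self):
        seq = _periodic_labels(4000, seed=14)
        res = aif_peak_test(seq, [40.0], n_surrogates=10, seed=140)
        assert abs(res.p_value - 1 / 11) < 1e-12  # beats all 10 surrogates

    def test_window_outside_lag_range_errors(self, generic_model):
        seq = markov_surrogate(generic_model, 3000, seed=15)
        with pytest.raises(ValueError):
            aif_peak_test(seq, [999.0], max_lag_ms=1000.0, seed=0)

    def test_group_mode_one_sided(self):
        p, sig = aif_peak_test_group([0.9, 0.8, 0.85], [0.1, 0.2, 0.15, 0.12] * 5)
        assert p < 0.05 and sig
        p2, _ = aif_peak_test_group([0.1, 0.12], [0.1, 0.2, 0.15, 0.12] * 5)
        assert p2 > 0.2


class TestSignificantAIFPeaks:
    def test_noise_floor_wiggles_excluded(self, generic_model):
        seq = markov_surrogate(generic_model, 5000, seed=16)
        curve = aif(seq, 200.0)
        band = aif_confidence_band(generic_model, 5000, 200.0, n=100, seed=17)
        peaks = significant_aif_peaks(curve, band)
        # a matched surrogate has no significant peaks (up to band miscoverage)
        assert peaks.size <= 2

    def test_periodic_sequence_peak_found(self):
        seq = _periodic_labels(6000, seed=18)
        curve = aif(seq, 200.0)
        band = aif_confidence_band(transition_model(seq), seq.n_samples, 200.0, n=100, seed=180)
        peaks = significant_aif_peaks(curve, band)
        assert peaks.size > 0 and peaks[0] == 40.0


class TestMarkovTests:
    def test_dof_by_order(self, generic_model):
        seq = markov_surrogate(generic_model, 10**4, seed=19)
        assert markov_test(seq, 0).dof == 9
        assert markov_test(seq, 1).dof == 36
        assert markov_test(seq, 2).dof == 144

    def test_order0_rejects_first_order_chain(self, generic_model):
        seq = markov_surrogate(generic_model, 10**4, seed=20)
        res = markov_test(seq, 0)
        assert res.rejected and res.p_value < 1e-6

    def test_order1_holds_on_first_order_chain(self, generic_model):
        # type-I error control: reject ~ alpha over replicates
        chains = markov_surrogate_batch(generic_model, 10**4, 60, seed=21)
        rej = np.mean(
            [
                markov_test(MicrostateSequence(labels=c, fs=FS, K=4), 1).rejected
                for c in chains
            ]
        )
        assert rej <= 0.15

    def test_order1_rejects_second_order_chain(self, second_order_sampler):
        tensor, sample = second_order_sampler
        chains = sample(tensor(eps=0.1), 10**5, 3, seed=22)
        for c in chains:
            assert markov_test(MicrostateSequence(labels=c, fs=FS, K=4), 1).rejected

    def test_bonferroni_correction_applied(self, generic_model):
        seq = markov_surrogate(generic_model, 3000, seed=23)
        res = markov_test(seq, 1, alpha=0.05, bonferroni_m=20)
        assert res.rejected == (res.p_value < 0.05 / 20)

    def test_short_sequence_warns_on_sparse_cells(self, generic_model):
        seq = markov_surrogate(generic_model, 240, seed=24)
        with pytest.warns(UserWarning, match="cell counts"):
            markov_test(seq, 2)

    def test_invalid_order_errors(self, generic_model):
        seq = markov_surrogate(generic_model, 1000, seed=25)
        with pytest.raises(ValueError):
            markov_test(seq, 3)

    def test_g_statistic_matches_contingency_oracle(self, rng):
        # order-0 G equals the classic likelihood-ratio statistic of the
        # pair-count contingency table
        labels = rng.integers(0, 4, 2000)
        seq = MicrostateSequence(labels=labels, fs=FS, K=4)
        res = markov_test(seq, 0)
        counts = np.zeros((4, 4))
        for a, b in zip(labels[:-1], labels[1:]):
            counts[a, b] += 1
        n = counts.sum()
        g = 0.0
        for i in range(4):
            for j in range(4):
                if counts[i, j] > 0:
                    expected = counts[i].sum() * counts[:, j].sum() / n
                    g += 2 * counts[i, j] * np.log(counts[i, j] / expected)
        assert abs(res.statistic - g) < 1e-8
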