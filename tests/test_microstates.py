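"""GFP, GFP-peak detection, polarity-invariant clustering, back-fitting, GEV."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from msdyn import (
    EEGRecording,
    MicrostateMaps,
    MicrostateSequence,
    align_group_maps,
    assign_canonical_labels,
    backfit,
    find_gfp_peaks,
    gev,
    gfp,
    make_topography_basis,
    modified_kmeans,
)
from msdyn.microstates import GFPSeries, _normalize_maps

FS = 250.0


def _planted_alternation(basis, n_per, rng, noise=0.0):
    """Topography samples cycling through the basis maps with random signs."""
    K, N = basis.shape
    reps = np.tile(np.arange(K), n_per)
    signs = rng.choice([-1.0, 1.0], size=reps.size)
    amp = rng.uniform(0.5, 2.0, size=reps.size)
    V = basis[reps] * (signs * amp)[:, None]
    if noise:
        V = V + noise * rng.standard_normal(V.shape)
    return V, reps


class TestGFP:
    def test_zero_topography(self):
        rec = EEGRecording(data=np.zeros((4, 10)) + [[1], [-1], [2], [-2]], fs=FS)
        rec.data[:, 3] = 0.0
        assert gfp(rec).values[3] == 0.0

    def test_two_channel_unit(self):
        rec = EEGRecording(data=np.array([[1.0], [-1.0]]), fs=FS)
        assert abs(gfp(rec).values[0] - 1.0) < 1e-14

    def test_matches_definition_oracle(self, rng):
        data = rng.standard_normal((7, 50))
        data -= data.mean(axis=0)
        rec = EEGRecording(data=data, fs=FS)
        g = gfp(rec).values
        for t in range(50):
            expected = np.sqrt(sum(v * v for v in data[:, t]) / 7)
            assert abs(g[t] - expected) < 1e-12

    def test_rereferences_with_warning(self, rng):
        rec = EEGRecording(data=rng.standard_normal((4, 20)) + 5.0, fs=FS)
        with pytest.warns(UserWarning):
            g = gfp(rec)
        assert np.all(g.values >= 0)


class TestFindGFPPeaks:
    def test_alternating_series(self):
        g = GFPSeries(values=np.array([0.0, 1.0, 0.0, 1.0, 0.0]), fs=FS)
        assert list(find_gfp_peaks(g)) == [1, 3]

    def test_monotone_series(self):
        g = GFPSeries(values=np.linspace(0, 1, 10), fs=FS)
        assert len(find_gfp_peaks(g)) == 0

    def test_rank_one_oscillation_rate(self):
        # |sin| has two maxima per cycle: a 10 Hz rank-1 field gives ~20 peaks/s
        t = np.arange(int(10 * FS)) / FS
        topo = np.array([1.0, -0.5, 0.25, -0.75])
        topo -= topo.mean()
        rec = EEGRecording(data=np.outer(topo, np.sin(2 * np.pi * 10 * t)), fs=FS)
        g = gfp(rec)
        find_gfp_peaks(g)
        assert abs(g.peaks_per_second - 20.0) <= 1.0


class TestModifiedKmeans:
    def test_planted_model_recovery(self, rng, basis4):
        V, truth = _planted_alternation(basis4.maps, 100, rng)
        maps = modified_kmeans(V, K=4, n_runs=5, seed=3)
        C = np.abs(basis4.maps @ maps.maps.T)
        r, c = linear_sum_assignment(-C)
        assert np.all(C[r, c] > 0.999)
        assert maps.gev_total > 0.999
        # label accuracy up to permutation
        seq = np.argmax((V @ maps.maps.T) ** 2, axis=1)
        acc = np.mean(c[truth] == seq)
        assert acc > 0.95

    def test_polarity_invariance(self, rng, basis4):
        V, _ = _planted_alternation(basis4.maps, 50, rng, noise=0.05)
        a = modified_kmeans(V, K=4, n_runs=3, seed=7)
        b = modified_kmeans(-V, K=4, n_runs=3, seed=7)
        C = np.abs(a.maps @ b.maps.T)
        r, c = linear_sum_assignment(-C)
        assert np.all(C[r, c] > 0.9999)
        assert abs(a.gev_total - b.gev_total) < 1e-12

    def test_k1_equals_leading_eigenvector(self, rng):
        V = rng.standard_normal((200, 8))
        V -= V.mean(axis=1, keepdims=True)
        maps = modified_kmeans(V, K=1, n_runs=1, seed=0)
        S = V.T @ V
        evals, evecs = np.linalg.eigh(S)
        lead = evecs[:, -1]
        assert abs(abs(maps.maps[0] @ lead) - 1) < 1e-8

    def test_explained_variance_monotone_within_run(self, rng, basis4):
        V, _ = _planted_alternation(basis4.maps, 60, rng, noise=0.3)
        trace = []
        modified_kmeans(V, K=4, n_runs=2, seed=5, ev_trace=trace)
        for run in {r for r, _, _ in trace}:
            evs = [ev for r, _, ev in trace if r == run]
            assert all(b >= a - 1e-12 for a, b in zip(evs, evs[1:]))

    def test_too_few_samples_errors(self, basis4):
        with pytest.raises(ValueError):
            modified_kmeans(basis4.maps[:2], K=4)

    def test_deterministic_given_seed(self, rng, basis4):
        V, _ = _planted_alternation(basis4.maps, 30, rng, noise=0.2)
        a = modified_kmeans(V, K=4, seed=11)
        b = modified_kmeans(V, K=4, seed=11)
        np.testing.assert_array_equal(a.maps, b.maps)


class TestGEV:
    def test_perfect_fit_gives_one(self, rng, basis4):
        V, truth = _planted_alternation(basis4.maps, 40, rng)
        rec = EEGRecording(data=V.T, fs=FS)
        seq = MicrostateSequence(labels=truth, fs=FS, K=4)
        total, per = gev(rec, basis4, seq)
        assert abs(total - 1.0) < 1e-12
        assert abs(per.sum() - total) < 1e-12

    def test_orthogonal_adversarial_gives_zero(self, rng, basis4):
        V, truth = _planted_alternation(basis4.maps, 40, rng)
        wrong = (truth + 1) % 4  # orthogonal map assigned everywhere
        rec = EEGRecording(data=V.T, fs=FS)
        total, _ = gev(rec, basis4, MicrostateSequence(labels=wrong, fs=FS, K=4))
        assert total < 1e-20

    def test_matches_brute_force_oracle(self, rng, basis4):
        data = rng.standard_normal((30, 120))
        data -= data.mean(axis=0)
        rec = EEGRecording(data=data, fs=FS)
        labels = rng.integers(0, 4, 120)
        seq = MicrostateSequence(labels=labels, fs=FS, K=4)
        total, per = gev(rec, basis4, seq)
        num = np.zeros(4)
        den = 0.0
        for t in range(120):
            v = data[:, t] - data[:, t].mean()
            g2 = np.mean(v**2)
            m = basis4.maps[labels[t]]
            corr = (v @ m) / (np.linalg.norm(v) * np.linalg.norm(m))
            num[labels[t]] += g2 * corr**2
            den += g2
        np.testing.assert_allclose(per, num / den, atol=1e-10)
        assert abs(total - num.sum() / den) < 1e-10

    def test_zero_gfp_errors(self, basis4):
        rec = EEGRecording(data=np.zeros((30, 10)), fs=FS)
        seq = MicrostateSequence(labels=np.zeros(10, int), fs=FS, K=4)
        with pytest.raises(ValueError):
            gev(rec, basis4, seq)


class TestBackfit:
    def test_scaled_signed_maps_recover_labels(self, rng, basis4):
        V, truth = _planted_alternation(basis4.maps, 30, rng)
        rec = EEGRecording(data=V.T, fs=FS)
        seq = backfit(rec, basis4)
        np.testing.assert_array_equal(seq.labels, truth)

    def test_rotating_two_map_field_recurrence(self, basis4):
        # polarity-ignoring fit makes a 10 Hz rotation recur every 50 ms
        t = np.arange(int(4 * FS)) / FS
        field = np.outer(basis4.maps[0], np.sin(2 * np.pi * 10 * t)) + np.outer(
            basis4.maps[1], np.cos(2 * np.pi * 10 * t)
        )
        seq = backfit(EEGRecording(data=field, fs=FS), MicrostateMaps(maps=basis4.maps[:2]))
        # label at t and t + 50 ms (half period, antipodal field) is identical
        shift = int(round(0.050 * FS / 2) * 2)  # 12 or 13 samples; use 12+1
        lab = seq.labels
        agree = np.mean(lab[25:-25] == np.roll(lab, 25)[25:-25])  # 100 ms, exact on grid
        assert agree > 0.99
        # and the label alternates within a cycle
        assert np.unique(lab).size == 2

    def test_matches_argmax_oracle(self, rng, basis4):
        data = rng.standard_normal((30, 80))
        rec = EEGRecording(data=data, fs=FS)
        seq = backfit(rec, basis4)
        for t in range(80):
            v = data[:, t] - data[:, t].mean()
            corr2 = [
                (v @ m / (np.linalg.norm(v) * np.linalg.norm(m))) ** 2
                for m in basis4.maps
            ]
            assert seq.labels[t] == int(np.argmax(corr2))

    def test_zero_variance_sample_propagates_previous_label(self, rng, basis4):
        V, truth = _planted_alternation(basis4.maps, 5, rng)
        V[7] = 0.0
        rec = EEGRecording(data=V.T, fs=FS)
        with pytest.warns(UserWarning):
            seq = backfit(rec, basis4)
        assert seq.labels[7] == seq.labels[6]


class TestAlignGroupMaps:
    def test_recovers_planted_permutation(self, rng, basis4):
        perms = [np.array([2, 0, 3, 1]), np.array([1, 3, 0, 2]), np.arange(4)]
        subjects = [
            MicrostateMaps(maps=basis4.maps[p] * rng.choice([-1, 1], 4)[:, None])
            for p in perms
        ]
        group = align_group_maps(subjects, n_runs=5, seed=1)
        C = np.abs(basis4.maps @ group.maps.T)
        r, c = linear_sum_assignment(-C)
        assert np.all(C[r, c] > 0.999)

    def test_single_subject_identity(self, basis4):
        group = align_group_maps([basis4], n_runs=3, seed=0)
        np.testing.assert_allclose(np.abs(np.diag(group.maps @ basis4.maps.T)), 1.0, atol=1e-9)

    def test_group_maps_beat_single_subjects(self, rng, basis4):
        noisy = []
        for _ in range(6):
            noise = 0.25 * rng.standard_normal(basis4.maps.shape)
            m = _normalize_maps(basis4.maps + noise)
            noisy.append(MicrostateMaps(maps=m))
        group = align_group_maps(noisy, n_runs=5, seed=2)
        C = np.abs(basis4.maps @ group.maps.T)
        r, c = linear_sum_assignment(-C)
        group_r = C[r, c].mean()
        subj_rs = []
        for s in noisy:
            Cs = np.abs(basis4.maps @ s.maps.T)
            rs, cs = linear_sum_assignment(-Cs)
            subj_rs.append(Cs[rs, cs].mean())
        assert group_r > max(subj_rs)

    def test_inconsistent_montage_errors(self, basis4):
        other = make_topography_basis(20, 4, seed=1)
        with pytest.raises(ValueError):
            align_group_maps([basis4, other])


class TestEndToEndInvariances:
    def test_polarity_and_scale_invariance(self, rng, basis4):
        data = rng.standard_normal((30, 400))
        data -= data.mean(axis=0)
        rec = EEGRecording(data=data, fs=FS)
        g1 = gfp(rec)
        p1 = find_gfp_peaks(g1)
        seq1 = backfit(rec, basis4)
        gev1, _ = gev(rec, basis4, seq1)
        for factor in (-1.0, 3.7):
            rec2 = rec.copy_with(data=factor * data)
            g2 = gfp(rec2)
            p2 = find_gfp_peaks(g2)
            np.testing.assert_allclose(g2.values, abs(factor) * g1.values, rtol=1e-12)
            np.testing.assert_array_equal(p1, p2)
            seq2 = backfit(rec2, basis4)
            np.testing.assert_array_equal(seq1.labels, seq2.labels)
            gev2, _ = gev(rec2, basis4, seq2)
            assert abs(gev1 - gev2) < 1e-12


def test_assign_canonical_labels_is_cosmetic(rng, basis4):
    relabeled = assign_canonical_labels(basis4)
    assert sorted(relabeled.labels) == ["A", "B", "C", "D"]
    # same set of maps, only reordered
    C = np.abs(relabeled.maps @ basis4.maps.T)
    assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-9)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_gfp_polarity_invariance_property(seed):
    """Negating the EEG leaves the GFP curve unchanged."""
    data = np.random.default_rng(seed).standard_normal((6, 40))
    data -= data.mean(axis=0)
    a = gfp(EEGRecording(data=data, fs=FS)).values
    b = gfp(EEGRecording(data=-data, fs=FS)).values
    np.testing.assert_allclose(a, b, atol=1e-12)
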