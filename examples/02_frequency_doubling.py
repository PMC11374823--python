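"""Frequency doubling: a 10 Hz field produces 50 ms microstate recurrence.

A rotating alpha field inverts polarity every half cycle; since back-fitting
ignores polarity, the same microstate label returns after 50 ms, i.e. at
twice the EEG frequency.  The autoinformation function (AIF) of the label
sequence makes this visible, and the AIF peak test quantifies it against
first-order Markov surrogates.
"""

import msdyn as m
from msdyn.pipeline import AnalysisConfig, preprocess

spec = m.SimulationSpec(state="W", duration_s=60, snr=10, seed=42, osc_freq_hz=10.0)
basis = m.make_topography_basis(30, 4, seed=43)
rec, truth = m.simulate_rotating_field(spec, basis.maps[:2])
rec = preprocess(rec, AnalysisConfig())

g = m.gfp(rec)
peaks = m.find_gfp_peaks(g)
maps = m.modified_kmeans(rec.data.T[peaks], K=4, n_runs=5, seed=44)
seq = m.backfit(rec, maps)

curve = m.aif(seq, 1000.0)
band = m.aif_confidence_band(m.transition_model(seq), seq.n_samples, 1000.0, n=100, seed=45)
sig = m.significant_aif_peaks(curve, band)
res = m.aif_peak_test(seq, [50.0, 100.0], n_surrogates=10, seed=46)

print(f"planted recurrence interval : {truth.info['recurrence_interval_ms']:.0f} ms")
print(f"first significant AIF peak  : {sig[0]:.0f} ms")
print(f"next peaks                  : {[f'{x:.0f}' for x in sig[1:4]]} ms")
print(f"peak test at 50/100 ms      : p = {res.p_value:.4f} "
      f"({'significant' if res.significant else 'not significant'})")

# The first AIF peak sits at half the 100 ms oscillation period (on the 4 ms
# lag grid), and the windowed AIF area at 50/100 ms exceeds all 10 Markov
# surrogate values: the recurrence is not explainable by one-step transition
# statistics.
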