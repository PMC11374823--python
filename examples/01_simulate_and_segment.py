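"""Simulate a wakefulness recording and segment it into microstates.

Builds 105 s of synthetic 30-channel "wake" EEG (9.6 Hz alpha regime over a
1/f background), clusters the GFP-peak topographies into K=4 maps and
back-fits them at every sample.
"""

import msdyn as m

spec = m.SimulationSpec(state="W", duration_s=105, seed=7)
rec, truth = m.simulate_state(spec)

g = m.gfp(rec)
peaks = m.find_gfp_peaks(g)
maps = m.modified_kmeans(rec.data.T[peaks], K=4, n_runs=5, seed=8)
maps = m.assign_canonical_labels(maps)
seq = m.backfit(rec, maps)
gev_total, gev_per_map = m.gev(rec, maps, seq)
mmd_ms, _ = m.mean_durations(seq)

print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
print(f"GFP peaks per second : {g.peaks_per_second:.1f}")
print(f"mean duration        : {mmd_ms:.1f} ms")
print(f"total GEV            : {gev_total:.2f}")
for label, v in zip(maps.labels, gev_per_map):
    print(f"  GEV map {label}          : {v:.2f}")

# PPS tracks the tempo of the dominant rhythm (two GFP peaks per alpha
# cycle), mean durations of ~20-25 ms reflect unsmoothed per-sample fitting,
# and the four maps explain roughly 60% of the GFP-weighted spatial variance.
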