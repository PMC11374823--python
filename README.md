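# msdyn — frequency analysis of EEG microstate sequences

EEG microstates are transient, quasi-stable scalp field topographies; a
multichannel recording can be compressed into a sequence of a few (typically
K = 4) microstate labels, one per sample.  `msdyn` segments multichannel EEG
into such label sequences and asks a question the usual transition-matrix
summaries cannot answer: **do microstates recur periodically, and at which
frequencies?**  It was built for the wake/NREM-sleep setting, where the
dominant EEG rhythm moves from alpha (~10 Hz) through spindles (~12.5 Hz)
down to delta (~1 Hz), and ships a synthetic generator that emulates those
regimes so every stage can be validated against planted ground truth.

## The method

**Segmentation.**  After band-pass filtering (0.5–20 Hz, zero-phase 6th-order
Butterworth) and average referencing, the global field power

GFP(t) = sqrt( (1/N) Σᵢ vᵢ²(t) )

marks, at its local maxima, instants of stable topography.  Topographies at
GFP peaks are clustered with a polarity-invariant ("modified") k-means whose
assignment and centroid updates use squared spatial correlation, so a map and
its negation are the same state; group maps across subjects come from a full
label-permutation alignment.  Labels are then assigned at *every* sample by
maximal squared correlation — no temporal smoothing — because smoothing wipes
out exactly the fast recurrence structure under study.

**Sequence statistics.**  GFP peaks per second, mean microstate duration,
GFP²-weighted global explained variance, the transition model
(π, T) with Tᵢⱼ = P(X_{t+1}=j | X_t=i), and the relaxation time
T_relax = 1/(1 − |λ₂(T)|).

**Information dynamics** (all in bits, invariant to relabeling):
Shannon entropy H(X) = −Σ P(Xₜ=i) log₂ P(Xₜ=i); the finite entropy rate
h = H(X_{t+1} | X_t^{(k)}) with history k = 6 samples (24 ms); and the
autoinformation function

AIF(τ) = H(X_{t+τ}) − H(X_{t+τ} | X_t),

the time-lagged mutual information — the categorical analogue of the
autocorrelation function.  Because oscillations invert polarity every half
cycle and the fitting ignores polarity, a rhythm at frequency f makes
microstates recur at 2f: AIF peaks at multiples of 1/(2f).

**Hypothesis tests.**  The null model is the first-order Markov chain fitted
to the sequence.  `msdyn` provides seeded Markov surrogate generation,
pointwise AIF confidence bands (n = 500, α = 0.05), an AIF peak test
comparing the normalized AIF area in ±8 ms windows around candidate lags
(taken from the first two ACF extrema of the EEG's first principal component)
against n = 10 surrogates via an exact one-sided Mann–Whitney procedure, and
likelihood-ratio (G) tests of the Markov property of order 0, 1 and 2.

## Worked example

`examples/02_frequency_doubling.py` plants a 10 Hz rotating field (two
orthogonal topographies driven by narrowband quadrature components) at SNR
10, segments it, and inspects the label sequence:

```
planted recurrence interval : 50 ms
first significant AIF peak  : 48 ms
next peaks                  : ['76', '100', '124'] ms
peak test at 50/100 ms      : p = 0.0043 (significant)
```

The first AIF peak lands at half the 100 ms oscillation period (48 ms is the
closest 4 ms lag-grid neighbour of 50 ms): the microstates run at twice the
EEG frequency.  The peak test's windowed AIF areas at 50 and 100 ms beat all
10 Markov surrogates, so the recurrence is not explained by one-step
transition statistics.  `examples/03_sleep_depth_slowing.py` runs the full
pipeline across simulated vigilance states:

```
 state    PPS  MMD ms  T_relax  h bits
     W   18.9    24.2     4.68   0.835
    N1   18.6    21.8     4.80   0.877
    N2   18.9    27.1     5.00   0.769
    N3   15.3    67.9    16.18   0.393
```

From wake to deep sleep the dynamics slow (longer durations, larger
relaxation time) and become more predictable (lower entropy rate).

## Command line

A thin CLI mirrors the stages: `msdyn simulate | segment | stats | infodyn |
test-aif-peaks | test-markov | run | run-group`.  Recordings travel as
channels × samples CSV (JSON sidecar with the sampling rate) or EDF; reports
are JSON plus two-column curve CSVs.

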