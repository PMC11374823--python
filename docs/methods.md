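# Methods

This note records the model assumptions, estimator conventions, parameter
defaults and design decisions behind `msdyn`, and what the synthetic-data
validation does and does not establish about real EEG.

## Signal path

Recordings are `channels × samples` voltage matrices (µV) with a declared
sampling rate; all study-condition defaults assume 250 Hz.  Preprocessing is
a zero-phase band-pass (Butterworth, design order 6, applied
forward–backward so the net phase response is zero and microstate timing is
untouched; the effective roll-off is therefore twice the design order)
followed by average referencing.  Band edges default to 0.5–20 Hz: the low
edge keeps delta content relevant in deep sleep, the high edge excludes
EMG-prone frequencies.

The multichannel spectrum is summarized by the first principal component of
the channel covariance (channel means removed; the eigenvector's
largest-magnitude entry is made positive so the sign is reproducible).  Its
PSD uses Welch's method with a Hann window of 4096 ms and — unstated choices
in the underlying convention, fixed here — 50% overlap and per-segment mean
removal; peak locations are insensitive to both.  The ACF uses the biased
(1/n) estimator, which guarantees |r(τ)| ≤ r(0) = 1 and a nonnegative
spectrum.  Band powers are trapezoidal PSD areas with interpolated band
edges, so disjoint bands partition the total area exactly.

Extremum detection is a strict three-point criterion; plateaus report their
first sample; lag 0 is never an extremum.  One consequence worth noting: a
pure 10 Hz tone at 250 Hz has its ideal ACF minimum at 50 ms = 12.5 samples,
*between* two grid points, and the biased estimator resolves it to 48 ms.
Lags are therefore only ever meaningful to ±1 lag step (4 ms).

## Microstate segmentation

Clustering input is the set of topographies at strict GFP maxima; back-fitting
is per sample over the whole recording.  These are deliberately different
sample sets: peaks give clean cluster input, per-sample fitting preserves the
sequence's full temporal bandwidth (no smoothing, no peak-to-peak label
interpolation — either would low-pass the very recurrence structure the AIF
is meant to detect, and mean durations are correspondingly shorter than in
smoothing pipelines).

The modified k-means is polarity-invariant: assignment maximizes squared
spatial correlation, and each centroid update takes the leading eigenvector
of its members' scatter matrix.  Convergence is declared at a relative
explained-variance change below 1e-6 (cap: 500 iterations); initialization
samples K topographies without replacement from a seeded generator; of
`n_runs = 5` restarts the run with the highest explained variance wins.
Dead clusters are reseeded from the worst-fitted sample.  Zero-variance
topographies are excluded from clustering; during back-fitting they inherit
the previous label (label 0 at the start) with a warning.  Ties in the
assignment break toward the lowest label index.

Group maps solve a permutation alignment: per subject, the label permutation
(sign-free, Hungarian assignment on squared correlations) that best matches
the current group maps; per label, the group map is updated as the leading
eigenvector of the stack of subjects' aligned maps.  The objective — mean
squared correlation of subject maps to their group map — is the "shared
variance" this implementation reports; 20 seeded restarts keep the best run.
The canonical A–D letters are assigned by maximal |correlation| against
harmonic templates on an idealized circular montage; this is cosmetic and no
label-independent metric depends on it.

GEV follows the GFP²-weighted convention:
GEV = Σₜ GFP(t)² corr²(vₜ, map_{L(t)}) / Σₜ GFP(t)², with correlations on
channel-mean-removed vectors.

## Sequence statistics

The transition matrix is the per-sample maximum-likelihood estimate with
self-transitions included — under per-sample, unsmoothed labeling T is
strongly diagonal, unlike conventions that collapse runs first.  Unseen rows
fall back to uniform with a warning.  Mean durations include the (possibly
truncated) first and last runs.  The relaxation time is 1/(1 − |λ₂|) with
eigenvalues ordered by modulus: T need not be reversible, complex pairs
occur, and the modulus is what governs the geometric mixing rate.  A zero
gap (frozen chain) reports an infinite relaxation time.

## Information dynamics

All entropies are plug-in (maximum-likelihood) estimates in bits, with
overlapping block counts (stride 1).  No bias correction is applied: for an
iid K-ary sequence of length n the plug-in mutual information has expectation
≈ (K−1)²/(2 n ln 2), and every inference against this bias is made by
comparison with Markov surrogates *of the same length*, which carry the same
bias.  The finite entropy rate is H(blocks of k+1) − H(blocks of k); the
default history k = 6 samples (24 ms) balances resolution against the
K^(k+1) cell counts — a warning fires when the sequence is shorter than
10·K^(k+1) samples, which is the norm at K = 4 and typical segment lengths
and simply flags that absolute values are biased downward.

Because the plug-in AIF fluctuates at its bias floor, *reading off peak
locations* uses the surrogate band: `significant_aif_peaks` returns strict
local maxima only where the curve exceeds the upper 95% band of the Markov
ensemble.  Raw `local_extrema` on an AIF will happily report bias-floor
wiggles.

A mathematical point that shaped both the generator and the tests: mutual
information is invariant under bijections of the alphabet, so for a
*deterministic* periodic sequence a time shift acts as a label permutation
and the AIF sits at its ceiling at **every** lag — deterministic rotation
produces no 1/(2f) peak structure.  Observable AIF peaks require stochastic
phase/amplitude: the quadrature components must decorrelate away from
half-period lags so that label MI tracks |ACF|².

## Surrogates and tests

Markov surrogates sample X₀ ~ π, X_{t+1} ~ T[Xₜ] from a seeded generator
(bit-reproducible; a vectorized batch sampler serves bands and calibration).
AIF confidence bands are pointwise (α/2, 1−α/2) percentiles over n = 500
surrogates (pointwise, not simultaneous — a family-level statement needs the
peak test).

The AIF peak test statistic is the trapezoidal AIF area in ±8 ms (2-sample)
windows around the candidate lags, normalized by the AIF area over (0,
1000 ms] (lag 0 excluded — AIF(0) = H(X) would dominate).  Candidate lags
default to the first two ACF extrema of the companion EEG whose |r| clears
the 4/√n estimation-noise floor; if the second extremum exceeds the lag
range, only the first is used.  Significance compares the m per-window
empirical areas against the n·m pooled surrogate areas with an exact
one-sided Mann–Whitney U test; for m = 1 this reduces to the exact rank
p-value (1 + #{S_surr ≥ S_emp})/(n + 1), whose smallest attainable value at
n = 10 is 1/11 — single-lag tests at n = 10 can therefore never clear
α = 0.05, which is why the per-window arrangement is the default.  Measured
on matched Markov inputs the test rejects at ≈ 4–5% for α = 0.05.

Markovianity tests are likelihood-ratio G statistics on contiguous tuple
counts: order 0 tests X_{t+1} ⟂ Xₜ (dof (K−1)²), order 1 tests
X_{t+1} ⟂ X_{t−1} | Xₜ (dof K(K−1)²), order 2 conditions on the last two
labels (dof K²(K−1)²), with χ² asymptotics and Bonferroni correction across
the recordings of a batch.  Zero cells contribute zero; a warning fires when
expected cell counts are mostly below 5.  Calibration at length 10⁴ over
1000 replicates: 5–6% rejection at α = 0.05.  Power drops sharply with
length: second-order structure of modest strength is essentially invisible
in spindle-length (~240 sample) segments while being detected with certainty
at 10⁵ samples — short segments "passing" a Markov test is a statement about
power, not about the process.

## Synthetic data: what it emulates, and what it does not

The generator plants K = 4 exactly orthonormal, zero-mean topographies
(low-order harmonics on a circular montage, mixed by a seeded orthogonal
transform).  Oscillations are rotating fields x(t)·m₁ + y(t)·m₂ with x, y
independent narrowband Gaussian processes centered on the state frequency
(Gaussian spectral envelope, bandwidth f/5; bandwidth 0 recovers the
deterministic sin/cos pair, useful for closed-form checks but — see above —
not for AIF peak structure).  Because one narrowband rotation is confined to
a 2-D plane of channel space, the rotation plane hops among map pairs on a
~1 s epoch grid, spreading data over all four maps without touching the
within-epoch periodicity.  The 1/f background (spectrally shaped Gaussian
noise, exponent 1) is spatially smoothed over the montage (Gaussian kernel,
σ = 10% of the ring) — spatially white background would push total GEV far
below realistic values.

State recipes: W rotates at 9.6 Hz with SNR 0.5 (first-PC spectral maximum at
the alpha bump, relative alpha ≈ 0.5, GEV ≈ 0.6); N1 is 1/f background only;
N1_theta rotates at 6.6 Hz; N2 superimposes Hann-enveloped 12.5 Hz bursts of
544–1844 ms at ~6/min; N2_spindle is one isolated burst-length segment; N3
rotates at 1.1 Hz with its amplitude calibrated in closed loop until the
0.5–3 Hz band holds ≥ 84% of the 0.5–20 Hz first-PC power.  Durations default
to 158 s (range 105–210 s); tests that need tight map recovery use 200 s so
each map anchors a well-sampled cluster.

Limitations to keep in mind when transferring conclusions to real data:
topographies come from a circular montage, not a head model; the planted
maps are exactly orthogonal, which real microstate maps are not; the N1
recipe models only the *absence* of rhythm, not N1's spectral slowing — so
simulated N1 entropy rates sit slightly above W, whereas empirically the
order is reversed; sleep graphoelements beyond spindles (K-complexes, vertex
waves) are not modeled; and a 1/f background is itself long-memory, so even
"featureless" simulated recordings are genuinely non-Markovian at long lags.
Passing tests demonstrate estimator and pipeline correctness under these
controlled conditions, not physiological completeness.

## Problem sizes and numerics

Default analysis sizes follow the study conditions (250 Hz, 105–210 s,
max lag 1000 ms, 500-surrogate bands, 10-surrogate peak tests).  The test
suite scales simulations to what each property needs: oracle-equivalence
fixtures use ≤ 1000 samples at 1e-10 tolerance; consistency checks use 10⁵–10⁶
sample chains at 0.01 tolerance; calibration uses 1000 replicates of length
10⁴.  Seeds are explicit everywhere; identical (inputs, config, seed) produce
bit-identical sequences, ensembles and p-values.
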