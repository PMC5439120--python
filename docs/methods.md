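# Methods

`mmrtf` implements a probabilistic time–frequency analysis of auditory
oddball EEG. The pipeline turns single-trial recordings from one block (one
"contrast" of a standard and a deviant sound) into a per-subject
time–frequency probability surface (the MMR_TF), combines subjects and
contrast conditions with a modified joint DISTATIS, and extracts
spectral–temporal features, centroids and a scalar surprise statistic from
the group result. A synthetic sleep-EEG simulator with a known deviant
response provides ground truth for every stage.

## The estimator, stage by stage

**Preprocessing.** Continuous EEG is band-passed 2–50 Hz with a zero-phase
windowed-sinc FIR filter. The transition bands are chosen so the measured
rolloff at the band edges is a gentle ~24 dB/octave (high-pass transition
~1.8 Hz wide, low-pass up to ~110 Hz wide, capped below Nyquist); the odd,
symmetric kernel is applied with a centered convolution, so the group delay
is exactly compensated. Re-referencing is to the common average of the 11
scalp channels or to linked mastoids ((M1+M2)/2); the analysis montage is Cz
against linked mastoids. Epochs span −500…1500 ms around stimulus onset
(inclusive endpoints; 2001 samples at 1000 Hz), baseline-corrected to the
pre-stimulus interval (closed on the left, open on the right).
Joint-probability artifact rejection scores each trial per channel by the
summed negative log of the empirical probability of its sample amplitudes
(histogram over all trials' samples, Rice-rule bin count) and flags trials
whose score exceeds mean + 2.5 SD. The mask is label-blind and the data are
never modified.

**Whitening.** Each retained block (trials × time) is centered and whitened
along the trial dimension: trials are the observations, the time points the
variables. Centering subtracts the across-trial mean (the average evoked
response; deviant-minus-standard differences are unaffected). PCA of the
time-point covariance yields an eigen-spectrum shaped by the 1/f EEG
background; all components explaining at least 0.01% of the total variance
are retained, rescaled to unit variance, and mapped back to the original
coordinates (ZCA). The net effect is a spectral flattening: the background
no longer dominates the slow scales of the wavelet transform. We read the
whitening axis this way (rather than whitening the trial-space covariance)
for two reasons: the 0.01% variance threshold only bites on the temporal
eigen-spectrum, and trial-space whitening would normalize the evoked
component's variance to unity, making every downstream quantity invariant
to response amplitude — we verified empirically that trial-space whitening
produces surfaces that are essentially identical for burst amplitudes
spanning two orders of magnitude, which would make any SNR-dependent result
impossible.

**Time–frequency transform.** A 6-cycle complex Morlet CWT (carrier
ω0 = 6) on 128 log-spaced scales with center frequencies 1.94–48.40 Hz,
computed on the full epoch and only then truncated to −100…700 ms, with the
complex pre-stimulus mean (−100…0 ms) subtracted per trial and scale.
Coefficients follow the analytic-amplitude convention (PyWavelets' raw
output is rescaled per scale) so a pure sinusoid's ridge peaks at its own
center frequency. Trials whose total squared magnitude exceeds mean +
2.5 SD are dropped. Note a resolution limit that matters later: the
wavelet's temporal envelope SD is ω0/(2πf) ≈ 190 ms at 5 Hz, and the
cone-of-influence of the slowest scales (≈ 0.7 s) is wider than the 400 ms
margin between the kept window and the epoch edges, so the bottom octave
retains some edge leakage; the code warns about the affected scales.

**MMR_TF.** The signal estimate `M` is the squared complex modulus of the
mean over `n_boot` = 1001 bootstrap draws of (random deviant − random
standard trial); the error estimate `E` repeats this with label-blind pairs
from the whole block. Taking the complex mean before the modulus makes the
estimator sensitive to phase-consistent differences only. Per scale, `M`
and `E` are jointly divided by the root of their pooled squared sum
(Σ MM² + Σ EE² = 1 per scale), equating energy across scales. Each
normalized signal value is then replaced by its value under a
kernel-smoothed CDF of the pooled signal and error values, yielding the
probability surface. The smoothed CDF uses a Gaussian kernel with a
Silverman plug-in bandwidth evaluated on a 4096-point grid; an
empirical-CDF switch exists and doubles as the test oracle (the two agree
to < 0.02 at 10⁴ points).

**Group analysis (joint DISTATIS).** Each surface gives spectral and
temporal Gram matrices (p·pᵀ and pᵀ·p), double-centered with uniform masses
and normalized by their first eigenvalue. The −½ Ξ CP Ξᵀ centering of a
Gram matrix is negative semidefinite, so "first eigenvalue" is the one of
largest magnitude; dividing by it (negative) flips the sign and leaves a
PSD matrix with top eigenvalue exactly 1. Condition compromises are plain
means within condition; the grand compromise is the mean of the condition
compromises, so conditions are equi-weighted regardless of their size.
Eigenvectors with pvaf ≥ 1% (pvaf computed from square roots of
eigenvalues) are retained and renormalized to unit L2 norm (the printed
formula's sum-of-absolute-values denominator conflicts with the stated
"sum of squared values equal to one"; we follow the statement). Every
surface is projected onto the retained joint basis, weighted by the
relative contributions rc_F = λ¹_F/(λ¹_F+λ¹_T) and rc_T = 1 − rc_F; the
condition means and the grand mean of the projections are jointly min–max
rescaled to [0, 1] (the "relative probability"). The joint rescaling is an
interpretation — no formula is fixed by the estimator's definition — chosen
to keep condition surfaces comparable.

**Features.** The minimum bound `B` is the pointwise maximum over condition
projections; the quasi-likelihood estimate is qLE = CDF(B)²(G). A mask at
qLE ≥ 0.8 (configurable; the threshold is procedure-dependent) is labeled
into 8-connected components, split at the 12 Hz beta–gamma boundary, and
named by band and latency order. Per feature and condition, the temporal
and spectral distributions are the masked surface averaged across scales
and across time; the centroid is the joint maximum of the two
distributions. A local-maxima search splits composite features — nested:
two or more separated spectral peaks first (gamma vs beta, or a sweep's
dwell vs tail), then within each spectral part two or more temporal peaks
(onset vs offset, the theta-2/theta-2b pattern) — at the valley between
peaks, with ties broken toward the earliest/lowest-frequency point.

**Surprise.** S = −ln(dF/(C·dT)) with C = 1 and natural log. dF and dT are
estimated as the overlap coefficients (sum of pointwise minima after L1
normalization) of the theta-1 vs theta-2 spectral and temporal
distributions. This estimator is experimental: the definition of S fixes
neither how the probabilities of a frequency/latency difference are
estimated nor the constant, and the overlap reading is one admissible
choice. When the two distributions are nearly disjoint, dF is floored at
1e-12 and S saturates around 27.

## The simulator

`mmrtf.synth` emulates the recording conditions the pipeline targets:
1000 Hz sampling (study runs in this repository use 250 Hz; the analysis
band tops out at 48.4 Hz, so this halves nothing but runtime), an
11-channel 10–20 montage, ~600-trial blocks at 85% standard / 15% deviant
with no two deviants in succession (deviant count exact, arrangement
uniform via the stars-and-bars bijection), 1200 ms ISI, and spectrally
shaped Gaussian background noise: 1/f^α with α = 1.0 by default plus wide
delta (2–4 Hz) and theta (4–8 Hz) amplitude bumps (weights 0.5 / 0.3) and
an overall SD of 15 µV, giving the low-frequency-dominated background of
infant sleep EEG. The α default is a calibration choice: with a steeper
slope the whitening-flattened signal-to-noise profile tilts each burst's
wavelet ridge toward higher frequencies by more than 1 Hz, distorting
exactly the quantity the recovery studies measure.

Deviant trials additionally contain a response cascade of Hann-tapered,
phase-locked bursts projected through a dipolar scalp topography (vertex
positive, mastoids −0.5): gamma 34 Hz at 25 ms, beta 17 Hz at 60 ms,
theta-1 5 Hz at 70 ms and theta-2 6 Hz at 220 ms, the theta components
sweeping down (to ~2.2 and ~3 Hz) after their envelope peak — chirps carry
their center frequency exactly at the envelope peak, so the embedded
(frequency, latency) pairs are well-defined. Default amplitudes
(2.5/2.0/5.0/2.0 µV against the 15 µV background) are deliberately small —
single-trial evoked responses are far below the background in real
recordings — and are calibrated so that single-block probability surfaces
localize each component at ~600 trials; that calibration is part of the
generator's definition, as is the optional per-subject individualization
(Gaussian latency jitter, default SD 20 ms, and log-normal frequency
jitter, default 6% relative SD, zero-mean at the population level).
A smaller onset response common to all trials, per-trial phase jitter, and
custom topographies are available. What the simulator does not emulate:
sleep-stage transitions, ocular/movement artifacts, channel correlation
structure beyond the shared dipole, and habituation across trials — so
passing tests say nothing about robustness to those.

## What the synthetic studies show — and what they cannot

Block-level recovery is accurate: with the default cascade, the
scale-normalized difference surface of a single 600-trial block peaks
within a few scale steps and a few tens of milliseconds of each embedded
burst, and the probability surface puts p ≥ 0.95 at every embedded center
(the premise that single-subject MMR_TF maxima are supra-chance holds).

The group chain, however, has structural behaviors that bound what
centroid recovery can achieve, all of which we verified by targeted
simulation and none of which are implementation artifacts (the group
algebra is cross-checked against an independent dense implementation to
1e-8):

1. *Low-frequency rank advantage.* The per-scale unit-energy normalization
   gives the slowest scales — whose rows hold only one or two effective
   samples under the wavelet's temporal smoothing — systematically larger
   per-point values, and the pooled CDF ranks them near 1. The bottom
   octave therefore claims most of the top decile that a qLE ≥ 0.8 mask
   selects. The same emphasis is visible in the phenomenon the package
   models, where reported group features concentrate at 2–7 Hz and sweep
   down to the lower limit of the spectral axis.
2. *Signal/error floor asymmetry.* The signal estimator draws its pairs
   from ~90 deviants, the error estimator from all ~600 trials, so the
   signal estimate's bootstrap noise floor is ~1.8× larger in variance.
   Null signal values consequently rank above null error values, and the
   effect concentrates where (1) already dominates. One consequence:
   zero-amplitude control runs still produce supra-threshold qLE features
   in essentially every run — the qLE map is a *relative* likelihood over
   the plane, not a calibrated null test, and should not be used as one.
3. *Cross-condition dilution.* The grand compromise averages conditions,
   so compact features of a condition whose cascade is delayed relative to
   the others are diluted at their true location and the qLE mask shifts
   toward the cross-condition overlap, biasing masked centroids tens of
   milliseconds late.
4. *Theta resolution.* At 5–6 Hz the 6-cycle wavelet cannot temporally
   resolve components 150 ms apart; theta-1 and theta-2 merge unless their
   down-sweeping tails separate them diagonally, and even then the merged
   masks' centroids sit between the two dwells.

The acceptance suite contains an end-to-end recovery study (12 subjects ×
3 conditions × 600 trials, one condition delayed 100 ms) asserting centroid
recovery within ±1.5 Hz (±0.5 Hz for theta) and ±30 ms, and a null-control
study (20 zero-amplitude runs) asserting that no qLE ≥ 0.8 feature
survives. Both fail, for the reasons above, and are intentionally left
failing rather than weakened: they document the estimator's calibration
limits under exactly the conditions they prescribe.

## Numerical choices and degenerate inputs

- Smoothed CDFs: Gaussian kernel, Silverman bandwidth, 4096-point grid,
  linear interpolation, clipped to [0, 1]; degenerate (constant) pooled
  samples map everything to 0.5 (qLE: 0.25) with a warning.
- All-zero scales in the per-scale normalization are flagged and left at
  zero rather than divided.
- Eigenvector sign convention: largest-magnitude element positive.
- Rejection SDs equal to zero (identical trials) reject nothing; rejecting
  every trial raises an error naming the threshold.
- Per-(subject, condition) seeds derive from the master seed by a CRC32
  mix, so cohort runs are reproducible while blocks stay independent.
- Feature splitting uses peak prominence ≥ 0.25 of the distribution's range.

## Problem sizes

Default test and acceptance runs use 250 Hz sampling, 80–600 trials per
block, 101–501 bootstrap draws, and cohorts of 2–12 subjects; these sizes
are the package's own choice of simulation scale and are stated where used.
The estimator itself is independent of these choices apart from the
statistical effects documented above.
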