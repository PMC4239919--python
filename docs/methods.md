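# Methods

## Problem and signal model

The package classifies per-epoch driver vigilance from three channels: two
referential EEG derivations — Fpz-Cz ("EEG1", fronto-central) and Pz-Oz
("EEG2", parieto-occipital) — sampled at 100 Hz, and one respiration channel
at 1 Hz. Annotations use six vigilance levels, coded 6 (awake), 5 (slightly
drowsy), 4 (moderately drowsy), 3 (extremely drowsy), 2 (sleep), 1 (deep
sleep). The physiological rationale: alpha (8–13 Hz) activity rises as a
rested driver drifts toward sleep, beta (13–20 Hz) falls with vigilance,
theta (4–8 Hz) marks early drowsiness, delta (0–4 Hz) dominates sleep, and
breathing becomes less regular as sleep onset approaches. The three
drowsiest levels show no separable profile and are merged at classification
time, leaving four modeled classes (coded 6, 5, 4, 3).

## Pipeline stages

### Band-pass filtering

EEG channels are filtered to 0.1–40 Hz with a 4th-order Butterworth design.
The order and phase behaviour are free parameters of the method; the package
defaults to order 4 applied forward-backward (zero phase), standard EEG
practice that avoids phase distortion of band-limited features. Respiration
passes through unfiltered — its feature is a periodicity measure that
filtering would only distort. The digital (bilinear-transform) response is
verified against the closed-form Butterworth magnitude
`|H|² = 1/(1 + w^{2n})` on a grid up to 20 Hz and at the −3 dB edges; closer
to Nyquist the digital design is intentionally steeper than the analog
prototype (frequency warping), which only improves stop-band behaviour.

### Haar wavelet-packet decomposition

Each epoch's EEG is tiled into non-overlapping 128-sample segments (7 per
10 s epoch at 100 Hz; the trailing 104 samples are discarded). How the
segments tile an epoch is a design choice: non-overlapping from epoch start
with per-segment features averaged is the simplest scheme consistent with
one feature value per epoch.

Each segment is decomposed with the orthonormal Haar wavelet packet to level
6: 64 leaves of 2 coefficients, energy conserved to machine precision, exact
on dyadic lengths (no boundary handling needed). Natural (Paley) tree order
is not frequency order; the leaf at frequency position *f* sits at natural
position `gray(f) = f XOR (f >> 1)`, because every high-pass branch mirrors
the spectrum of its children. The ordering is validated against PyWavelets'
frequency-ordered packet tree and an explicit orthonormal transform matrix.

Band grouping (frequency-ordered, 1-based leaves): delta 1–5, theta 6–10,
alpha 11–17, beta 18–45. The beta group nominally labels 13–20 Hz but its
leaves span ≈13.3–35.2 Hz; the leaf indices are authoritative, the Hz labels
documentation. Leaves 46–64 (≈35–50 Hz) belong to no band and are excluded
from the four-band power total, so `PWR_total` is at most (and generally
below) the full segment energy.

A caveat worth stating: the Haar packet basis is Walsh-like, with heavy
spectral leakage. A pure sinusoid at a band's center leaves only ≈50–80 % of
its four-band energy in the hosting band (measured phase-averaged: delta
0.73, theta 0.82, alpha 0.50, beta 0.70). The band features are therefore
*mixtures* dominated by — not isolates of — their nominal bands. This is a
property of the chosen wavelet (picked for its low cost on mobile-class
hardware), and it does not prevent the downstream stages from separating
vigilance states, as the end-to-end tests show.

### Features (51 per epoch)

Per channel and per 128-sample segment, averaged (NaN-aware) over the
epoch's 7 segments:

* mean, standard deviation, skewness, kurtosis — population denominators
  (`1/n`); skewness and kurtosis normalised by σ³ and σ⁴ (normal ≈ 3);
* zero-crossing count — strict sign changes, zeros inheriting the previous
  sign;
* ABS per band — mean absolute wavelet coefficient of the band;
* REL per band — squared-coefficient band energy over the four-band total;
* four ratios, computed from the ABS values (their defining quotients):
  α/β, θ/β, (θ+α)/β, (θ+α)/(α+β);
* CGF and FV per band — mean and variance of the band's per-leaf energy
  distribution over leaf center frequencies. Granularity is per leaf (64
  frequency points), since the band-range formula assigns frequency meaning
  to leaves, not to individual coefficients within one.

RGPNG, the respiration regularity, is the height of the largest local
maximum at nonzero lag of the unit-normalised (biased) autocorrelation of a
trailing respiration window. The window length is a free parameter; the
default 60 s gives ~15 cycles of a 4 s breath, enough for a stable estimate
at a 1 Hz sampling rate (an epoch's own 10 samples are far too few). The
biased estimator tapers the peak by `(1 − lag/n)`, so even perfectly regular
breathing scores ≈0.93 at the default window — relative ordering, not the
absolute value, carries the information.

Degenerate inputs (flat segments, empty bands, zero-variance respiration)
yield NaN for the affected features plus a warning; one bad segment must not
abort a long recording. Selection drops NaN rows pairwise; classification
refuses NaN and expects callers to mask or impute.

### Mutual-information ranking

Features are discretised into equal-frequency bins (default 8, by stable
rank, ties keeping input order) and scored by plug-in MI in bits against the
*six-level* label — merging happens later, and the finer class variable
costs nothing here. Equal-frequency binning makes scores invariant under
strictly monotone feature transforms, appropriate for a feature set mixing
µV, Hz, Hz² and counts. The default of 12 selected features follows the
observed plateau of accuracy versus feature count. The plug-in estimator is
biased upward at small n (≈`(r−1)(c−1)/(2N ln 2)` bits); ranking only
compares features at equal n and binning, so the bias cancels to first
order.

### RBF-SVM classification

Features are z-standardised with training statistics. Multiclass is
one-vs-one with voting (ties break toward the drowsier class, then by a
small summed-margin term); each binary sub-problem stores its own support
vectors, signed dual coefficients and intercept. (σ, C) are chosen jointly
on a log grid by stratified 5-fold cross-validated accuracy — the kernel
width cannot be fixed a priori across feature sets, and C matters once
classes overlap. The kernel exponent is negative,
`exp(−‖x−x'‖²/(2σ²))`: the positive-exponent variant diverges with distance
and is not a kernel.

**Support-vector pruning.** The model is compressed by keeping the
`ceil(fraction · n_SV)` support vectors with the largest |dual coefficient|
per binary sub-problem (default fraction 0.30) — the dual solution weights
each vector's influence on the decision function. Naively dropping vectors
breaks the dual balance `Σ αᵢyᵢ = 0` and biases every decision value, so the
retained coefficients are rescaled per sign group to restore the balance;
the operation is exact at fraction 1. Refitting on the retained vectors was
evaluated and rejected: it moves the boundary substantially on separable
problems.

**Evaluation** reports overall accuracy plus macro-averaged one-vs-rest
sensitivity and specificity (percent) with the confusion matrix. The
train/test split is contiguous in time (first 70 % / last 30 %) to avoid
temporal leakage between neighbouring epochs of one recording.

**Alarm.** An epoch classified at or below the threshold class (default
"moderately drowsy", 4) raises an alarm flag.

## The synthetic-data generator

No recordings were available to ship, so the generator provides labeled
ground truth with the right statistical ordering:

* **States.** A first-order Markov chain over the six levels; the default
  transition matrix is a nearest-neighbour walk with self-persistence 0.8,
  started at awake — vigilance drifts rather than jumps.
* **EEG.** Per epoch, a sum of four sinusoidal oscillators at the band
  midpoints (2, 6, 10.5, 16.5 Hz) with uniformly random phase per epoch and
  per-level amplitudes (µV), plus Gaussian background noise of 3 µV split
  equally between white and 1/f-shaped components. The default amplitude
  table encodes the qualitative trends — alpha 8→13 µV rising from awake to
  moderately drowsy then receding, beta 10→3 µV falling monotonically, delta
  8→22 µV growing into sleep, theta rising early — with the parieto-occipital
  channel carrying the trends slightly more strongly.
* **Respiration.** A sinusoid of 4 s base period whose phase accumulates
  Gaussian per-cycle jitter growing from 0.05 rad (awake) to 0.70 rad (deep
  sleep), so the autocorrelation peak decays with drowsiness.

What it does **not** emulate: real EEG morphology (spindles, K-complexes,
vertex waves), artifacts (EMG, EOG, electrode movement), inter-subject
variability, apneic respiration events, or any coupling between channels
beyond the shared state. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it is pointed at — not clinical
performance on human recordings.

## Problem sizes and numerical choices

* End-to-end checks use 900-epoch (2.5 h) recordings, a 70/30 contiguous
  split, 12 selected features, 5-fold CV on a 5×3 (σ, C) grid, repeated over
  5 seeds; the ranking-recovery check uses 500 epochs × 51 features × 20
  seeds. These sizes give stable statistics while keeping the full suite in
  the low minutes on one CPU.
* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from one global seed, and identical seed + configuration
  reproduces recordings and feature CSVs byte-for-byte.
* EDF output is 16-bit with per-channel physical bounds rounded outward to
  the header's 8-character fields; round-trip error is bounded by the
  quantisation step (≈1.5 × 10⁻³ µV per 100 µV of range).
* Energy-conservation and transform-equivalence assertions use 1e-9
  absolute/relative tolerance; entropy/MI identities 1e-12.

## Known limitations

* The Haar band features are leaky mixtures (see above); swapping in a
  longer wavelet would sharpen bands at higher per-segment cost.
* The MI estimator is plug-in; no bias correction or permutation calibration
  is applied beyond what the tests do.
* Pruning keeps intercepts fixed; at very small fractions the rebalanced
  approximation will eventually degrade (the default 0.30 is validated).
* The 128-sample segmentation discards ~10 % of each epoch; alternatives
  (overlap, Hamming-windowed sub-segments) are deliberately out of scope.
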