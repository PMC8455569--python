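# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecgfusion`, in the spirit of a package reference manual: what the
code assumes, why the defaults are what they are, and what the tests do
and do not demonstrate.

## Signal model and synthetic data

A heartbeat is modelled as five Gaussian bumps (P, Q, R, S, T), each with
an amplitude (mV), a width (Gaussian sigma, s) and a signed center offset
relative to the R peak (s).  Defaults:

| wave | amplitude | sigma   | offset   |
|------|-----------|---------|----------|
| P    | 0.15 mV   | 0.025 s | -0.16 s  |
| Q    | -0.10 mV  | 0.010 s | -0.030 s |
| R    | 1.00 mV   | 0.012 s | 0        |
| S    | -0.15 mV  | 0.010 s | +0.030 s |
| T    | 0.30 mV   | 0.055 s | +0.25 s  |

These respect normal-morphology envelopes (P duration about 100 ± 20 ms,
QT about 400 ± 40 ms) and make ground truth exact by construction: the
annotated index of each wave is its bump center rounded to the sample
grid.  RR variability is truncated-Gaussian (clipped at ±3 sd) so
non-overlap of consecutive beats can be guaranteed and checked.  Record
length is `ceil((lead_in + sum(RR_k) + lead_out) * fs)` with
`lead_in = lead_out = mean_rr/2`.

Corruption terms emulate the three disturbances the filtering stage
targets: a baseline-wander sinusoid (default 0.5 Hz, where respiratory and
electrode drift concentrates), powerline interference (50/60 Hz), and
broadband Gaussian noise.  One integer seed drives all random draws
(jitter, noise, phases); records are bit-reproducible.

What the generator does **not** emulate: inverted or biphasic T waves,
U waves, ectopic morphology changes, electrode pop artifacts,
non-stationary noise, or the beat-to-beat morphology variability of real
ECG.  Passing detection tests on this generator therefore demonstrates the
mechanics of the algorithm (block delimitation, gating, invariances,
noise robustness against additive corruption), not clinical performance;
the optional MIT-BIH benchmark script exists for the latter.

## Wavelet denoising

Scale selection uses the pseudo-frequency relation `F_a = Fc*Fs/2^a`.
`Fc` is computed from the wavelet function's dominant spectral peak
(0.714 for db4, commonly quoted as 0.7; an independent library value
cross-checks it in the tests).  The baseline scale `a*` minimizes
`|F_a - 0.5 Hz|`; the minimizing rule (rather than "first scale at or
below") keeps the selected scale stable regardless of whether the rounded
or the computed `Fc` is used — 9 at 360 Hz, 8 at 180 and 128 Hz.

Removing the scale-`a*` approximation alone leaves most of a 0.5 Hz drift
in place, because the drift frequency sits at the *center* of the
scale-`a*` detail band and db4's dyadic band responses are far from
brick-wall (measured: ~90% of a pure 0.5 Hz tone survives A9-only
removal).  The surgery therefore clears A(a*), D(a*) and the lower
half-band of D(a*-1), the last isolated by one further wavelet-packet
split.  This removes 0 - ~1.05 Hz at 360 Hz: 99.5% of a pure 0.5 Hz tone,
while retaining 97% of a 1.25 Hz tone (the heart-rate fundamental at
75 bpm) — clearing the whole of D(a*-1) instead would subtract a
beat-locked sinusoid comparable to the P amplitude and visibly distort P
and T.  In a detail branch the packet frequency ordering is mirrored, so
the original-frequency lower half is the split's detail sub-branch.

High-frequency suppression zeroes detail levels 1-3 (above ~22.5 Hz at
360 Hz, above the 8-20 Hz band that carries most QRS energy).

The decomposition uses **periodized** boundary handling, which makes the
transform orthonormal and every coefficient-zeroing step an exact
orthogonal projection: `denoise` is then linear and idempotent to machine
precision — exactly so on signal lengths divisible by `2^a*` (where no
internal padding occurs), with a small boundary residual otherwise.
`denoise` performs the baseline and high-frequency surgery in a single
decomposition for this reason.  The cost of periodization is a circular
boundary assumption, benign for records that start and end near the
isoelectric line.

When a record is too short for the planned depth, the depth is reduced
with a logged warning and only the approximation is cleared — at reduced
depth the detail bands no longer sit near the drift frequency, and
clearing them would remove signal content instead.

Consequences accepted by design: removing everything below ~1.05 Hz also
removes the DC and near-DC content of the ECG itself, so a noise-free
record is reproduced with correlation ~0.96, not ~1; and for a corrupted
record (1 mV drift + 0.1 mV noise) the signal-to-noise ratio against the
clean reference improves by >= 10 dB.

## Fractional Fourier transform

Convention: samples live on the centered dimensionless grid
`t_k = (k - n//2)/sqrt(n)`, so order 1 coincides with the centered unitary
DFT.  Orders 0, 1, 2, 3 (mod 4, tolerance 1e-9) route to exact
identity/DFT/reversal/inverse-DFT branches, avoiding the `cot(phi)`
singularities.  Other orders are reduced into [0.5, 1.5] by composing with
those exact branches and computed by the chirp-multiplication /
chirp-convolution / chirp-multiplication decomposition
(`cot = csc - tan(phi/2)`), on a 4x bandlimited-oversampled grid (FFT
zero-padding up, decimation down), with the convolution done exactly via
FFT.  Cost O(n log n).

A dense matrix built by direct Riemann quadrature of the continuous kernel
on the sample grid serves as the small-n test oracle.  Its validity band
is limited: outside reduced orders of roughly [0.5, 1.5] the kernel chirp
oscillates faster than the grid samples it and matrix rows alias, so
oracle-based tests stay inside that band and use inputs concentrated well
inside the grid.

Unitarity and order-additivity are properties of the continuous operator.
A finite-n discretization inherits them only on signals concentrated in
the central region of the time-frequency window: there this implementation
is unitary to ~1e-15 and additive against the oracle to better than 1e-3
(often 1e-6).  For full-band inputs such as white noise, energy genuinely
leaves the window under rotation — no finite discretization can preserve
it (the quadrature oracle itself deviates from unitarity at order one
there) — and the measured norm error is at the percent level.  The
property tests draw random smooth signals (sums of modulated Gaussians,
seeded) for the tight tolerances and document the loose white-noise
behavior separately.

Translation behaves the same way: the transform is exactly covariant only
under shifts compatible with its discretization (see Detector below).

## Detector

Pipeline: denoise -> isoelectric re-referencing -> R detection -> QRS
blanking -> FrFT enhancement -> P/T block generation -> PR/RT gating.

**Isoelectric re-referencing.**  Baseline removal also removes DC, leaving
the flat inter-beat segments at an arbitrary negative offset.  Squaring
would then treat that offset as energy and drown the small P deflection
(measured: the squared isoelectric plateau can exceed the squared P
remnant).  The median of an ECG trace sits on the isoelectric plateau, so
the detector subtracts it before enhancement and blanking; blanked
samples are then true isoelectric zeros.  The median is
amplitude-covariant, preserving the detector's scale invariance.

**R stage.**  The enhanced signal is `|F^0.01 . |^2` of the QRS-band
reconstruction (wavelet details 4-6 only, ~2.8-22.5 Hz at 360 Hz) rather
than of the full denoised trace: the wide, low-frequency T wave otherwise
crosses the event threshold at any `beta` in the conventional range
(suppressing it by threshold alone would need `beta ~ 0.9` against the
family convention of 0.08).  Restricting the R stage to the QRS band is
the same role the classic 8-21 Hz bandpass plays in the moving-average
detector lineage, here realized with the wavelet machinery already in
use.  Blocks at least W1 wide are kept (a config switch tightens this to
"equal to W1 within 20%"); each block's argmax is snapped to the nearest
local extremum (by magnitude, so lead polarity does not matter) of the
re-referenced denoised trace within ±W1/2, because the small rotation can
displace a maximum by a few samples; peaks closer than a 200 ms
refractory distance (the physiological upper bound on heart rate) are
merged keeping the larger amplitude.

**P/T stage.**  Blanking zeroes the closed interval [R-30, R+60] samples
at 360 Hz (0.083 s before to 0.167 s after; 91 samples per interior R);
the bounds scale with `fs` by rounding.  Blocks come from
`MA_peak(W3=55ms) > MA_wave(W4=440ms)` — W3 deliberately smaller than the
nominal P duration to cope with arrhythmic morphologies, W4 at the upper
end of the QT envelope.  Two guards make the comparison well-posed:
a relative epsilon (1e-9 of the enhanced maximum) so exact ties (constant
signal) are not decided by floating-point rounding, and an edge-guard of
W4/2 samples at each end of the record, where the zero-padded longer
window tapers more than the shorter one and would otherwise manufacture
blocks out of nothing.  The edge guard deliberately forfeits a peak
falling in the final ~0.22 s of a record (typically the last T).

Gating: a block maximum preceding its nearest following R by 0.10-0.30 s
is a P; one following its nearest preceding R by 0.18-0.48 s is a T; if
both gates match, the closer R wins; at most one P and one T per RR
interval (larger amplitude wins).  The gate minima are chosen strictly
above the blanking distances (0.083 / 0.167 s) so the step discontinuity
the blanking leaves can never itself be gated in as a peak — the
published method states only that "predefined" PR/RT windows are used,
without numbers; these values bracket the normal P-peak-to-R and
R-to-T-peak distances.  P/T argmaxes snap to the *signed* maximum of the
blanked trace within ±W3/2 (upright waves; inverted/biphasic T is out of
scope).  Moving-average sums follow the symmetric form `x(n+k)`,
`k = -(W-1)/2 .. (W-1)/2`, with every window forced to an odd sample
count at the record's rate.

**Matching.**  Detection vs reference uses a sorted two-pointer greedy:
walk both sequences, match the current pair when within 30 ms, else
advance the earlier side.  For 1-D interval tolerances this greedy attains
the maximum possible number of matches (a crossing-free exchange
argument); the test suite verifies equality with an independent maximum
bipartite matching (Kuhn's algorithm) on random instances.  A
smallest-distance-first greedy, by contrast, is *not* always optimal
(e.g. reference {0, 3}, detections {2, 5}, tolerance 2).

**Invariances.**  `detect_all` is exactly invariant under positive
amplitude scaling (every stage is either homogeneous or
amplitude-covariant).  Under time shifts it is exactly covariant for
shifts on the wavelet decimation lattice (multiples of `2^a*` samples —
the decimated DWT is only translation-covariant there); the test suite
asserts exact index shifts for 512- and 1024-sample paddings and exact R
covariance generally.  For arbitrary shifts, P/T indices can flutter by
~1 sample via the transform's boundary handling.  Detection quality on
the synthetic generator: clean records give 100% SE/+Pr for R and P and
>= 95% for T at any tested record length; R sensitivity stays 100% up to
at least 0.1 mV white noise; SE degrades monotonically with noise level.

## Features and classification

AR coefficients are estimated by Burg's method (stable on short
segments; the convention is `x(n) = sum a_i x(n-i) + e(n)` and the tests
verify parameter recovery on simulated AR processes).  Beat segments span
0.25 s before to 0.45 s after the R peak — one beat at every studied
sampling rate.  PR/RT intervals come from the nearest preceding P and
following T of each R; beats missing either are dropped and counted.
Optional spectral-shape features are the 32 level-4 db4 approximation
coefficients of the segment.  Sex is encoded M=0, F=1.  Feature
standardization is z-scored, fitted on the training split only (the
quoted SVM working point C = 65536, gamma = 2.44e-4 is only meaningful on
standardized features); age and sex are standardized along with the rest.
The split is stratified 70/30, seeded.  The MLP default is one hidden
layer of 32 units, 500 iterations, seeded.  Cross-rate work resamples
records to a common 128 Hz by polyphase band-limited resampling, with
annotation indices rescaled by rounding.

Classification metrics are the standard confusion-matrix definitions
(precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
accuracy the trace ratio), computed from the confusion matrix and checked
for internal consistency in the tests.

## Problem sizes used in the tests

The default suite and the acceptance script are sized for a desk run:
60-beat records (about 48 s at 360 Hz) for detection, n = 256 for
transform property checks, n = 5000 for AR recovery, 400 points for
classifier sanity, 200 random instances for the matching oracle.  The
whole suite completes in a few seconds.

## Known limitations

- Inverted, biphasic and merged-with-U T waves are out of scope (the P/T
  stage snaps to signed maxima).
- The last ~0.22 s of a record is a guard zone for P/T detection.
- Exact shift covariance holds on the wavelet decimation lattice, not for
  arbitrary shifts.
- The baseline-removal band (up to ~1.05 Hz at 360 Hz) slightly attenuates
  P/T amplitudes; detection is tested to tolerate this, but amplitude
  *measurements* downstream of `denoise` are biased low.
- Multi-lead fusion, real-time streaming, and reproduction of published
  database-level accuracy tables are not attempted here; the benchmark
  script supports the latter when records are available locally.
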