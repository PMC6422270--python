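# Methods

This note documents the models, numerical choices and design decisions
behind the package, and what the synthetic-data tests do and do not
establish about real recordings.

## The quantities and the law

For a 3D trajectory `r(t) = (x, y, z)` (mm; x anterior+, y superior+,
z lateral+, so the mid-sagittal plane is x–y), the pipeline estimates

- tangential speed `v = |ṙ|` (mm/s),
- curvature `κ = |ṙ × r̈| / |ṙ|³` (1/mm), computed via the cross product of
  the spline-consistent first and second derivatives,

and fits the power law `v = k·κ^(−β)` by ordinary least squares in log–log
coordinates.  Base-10 logarithms are used for reporting; `β` and `r²` are
invariant under the base, and `k = 10^intercept` then carries its
conventional magnitude (tens of mm/s for cm-scale articulatory movements).
The significance `p` is the two-sided significance of the Pearson
correlation of `log v` and `log κ`.  No curvature range is excluded
anywhere: with full 3D curvature, high-order differentiation and
rate-stratified fits, extremal curvature samples need no special handling.

Speeds below 1e-3 mm/s flag a sample as degenerate (the cross product of
nearly linearly dependent `ṙ`, `r̈` is dominated by rounding); degenerate
samples are excluded from regressions but kept, flagged, in the sample
tables.

## Conditioning chain

All stage parameters are configuration with these defaults:

| stage | parameter | default | notes |
|---|---|---|---|
| acquisition | sampling rate | 1250 Hz | device rate being emulated |
| decimation | total factor | 15 (stages 5 × 3) | larger first factor maximizes the first stage's transition band |
| decimation | FIR order | 30 per stage | equiripple; band edges at 0.8×/1.1× of the stage's output Nyquist; passband weighted 10:1 so in-band ripple stays well below 1%; taps normalized to exact unit DC gain; group delay compensated by centering |
| lowpass | Butterworth | order 4, 25 Hz | forward–backward (zero net phase), reflective padding of 3 filter orders |
| spline | roughness weight | 1e-3 (relative) | see below |
| segmentation | threshold | 20% of span peak velocity | onset = earliest crossing, offset = latest (multi-peak spans collapse to one movement) |
| segmentation | velocity floor | 1 mm/s | spans whose peak velocity stays below it are not movements |
| targeting filter | amplitude floor | 20% of the reference excursion | reference = median excursion of movements passing a coarse 20%-of-max screen, which keeps the rule robust when noise micro-spans outnumber movements (plain median is not) |
| subsampling | 5 per movement | interior fractions i/6 | endpoints carry v = 0, so only strictly interior equal-time samples keep log v defined; equal-arc-length spacing is available as a switch |
| triples | duration delimiters | 20% threshold | amplitude always uses the zero-to-zero path so `A` equals the figural excursion; both delimiters switchable |
| pipeline | edge trim | 1 movement per trial end | movements bordering the resting phases carry filter edge transients; counted, but excluded from regressions |

## Quintic splines and stencils

Displacement, velocity and acceleration must come from one analytic object:
curvature mixes first and second derivatives nonlinearly, so inconsistent
smoothing corrupts it.  Each axis is represented by a degree-5 B-spline with
a knot at every sample, fitted by penalized least squares.  With
knot-per-sample the least-squares problem is rank deficient (the C⁴ B-spline
space has four more degrees of freedom than samples); the penalty is on the
jumps of the fifth derivative across interior knots.  Its null space is
exactly the global quintic polynomials, so polynomial data is reproduced
with exact derivatives — the natural correctness oracle — while the
oscillatory modes that vanish at all samples carry large fifth-derivative
jumps and are suppressed.  An integrated-squared-fourth-derivative penalty
was rejected: its constrained minimizer among interpolants is not the
generating polynomial, which produces spurious boundary derivative error at
any weight.  The weight (default 1e-3, relative to the design matrix scale)
is a pure conditioning choice; its bias on band-limited signals is below
1e-6 relative.

The nine-point finite-difference stencils (first and second derivative,
eighth order of accuracy) are generated by exact rational Vandermonde
solves, so interior and shifted boundary stencils alike differentiate
polynomials up to degree 8 exactly.  Spline and stencil velocities agree to
well under 1% RMS on band-limited signals, which is asserted as an
invariant.

## Rigid alignment

Head correction estimates, per frame, the rigid transform mapping the
reference-sensor configuration onto its first-frame template using the
closed-form quaternion solution of the absolute orientation problem
(leading eigenvector of the 4×4 cross-covariance form), and applies it to
all channels; an optional constant occlusal transform follows (identity for
synthetic data, which is generated in the occlusal frame).  Degenerate
(collinear) reference configurations are rejected by a rank check.  The
implementation is cross-checked in tests against an independent SVD/Kabsch
solver and against a Monte-Carlo residual law (per-point RMS residual
`σ·sqrt(3 − 6/N)` for isotropic noise `σ` on N points).

## Segmentation conventions

The movement axis is the leading eigenvector of the trial's position
covariance.  Its sign is anchored so that closing movements (toward the
palatal constriction) have positive score velocity: the superior (y)
component is made positive when `|y| ≥ 0.1`, otherwise the dominant
component anchors the sign — a pure-threshold-on-y rule is unstable for the
nearly horizontal axes that repetitive coronal/dorsal loops produce.
Delimiters are refined to 1e-10 s by bracketed root finding on the spline
velocity.

## Gesture model and c factor

The standard dynamical model of one gesture is the critically damped linear
oscillator `ẍ = −k_s(x − target) − b ẋ`, `b = 2√k_s`.  Its closed form
(exposed as `gesture_closed_form`) implies `v* = ω·Δx/e` at `t = 1/ω` and a
20%-threshold duration `T = (u₂ − u₁)/ω` where `u·e^(1−u) = 0.2` has roots
`u₁ ≈ 0.0795`, `u₂ ≈ 4.01`.  Hence every critically damped gesture shares
`c = (v*/A)·(T/π) = (u₂ − u₁)/(eπ) ≈ 0.46`, consistent with the analytic
bound c ≤ 1/2; harmonic movements delimited at zero velocity attain exactly
c = 1/2.  The c-factor regression is through the origin (the model has no
additive constant); its r² is therefore the uncentered coefficient of
determination, and a with-intercept variant is available for diagnostics.

## Synthetic sessions: what they emulate

Each trial traverses a closed figural path so that `v = k·κ^(−β)` holds
*exactly* along the full 3D trajectory (arc-length reparameterization
`dt = ds·κ^β / k`), with one closing+opening cycle per metronome beat.

- **Template.** A "bent loop": an ellipse (aspect 0.62) whose vertical
  coordinate carries a third-harmonic bend.  The third harmonic makes the
  two half-cycles mirror images, so closing and opening movements see the
  same curvature range (a second-harmonic bend concentrates all curvature
  variation in one half, leaving the other half's fit degenerate).  Two
  circular arcs joined tangentially were rejected: their curvature jump
  would make the constructed speed profile discontinuous.
- **Rate coupling.** Syllable frequency = bpm/60; excursion falls linearly
  from 15 mm at the slowest to 10 mm at the fastest rate; the true exponent
  falls linearly from 0.46 to 1/3; the gain `k` follows from requiring one
  cycle per beat, so it rises with rate by construction.
- **Shape simplification.** The bend amplitude decays quadratically from
  0.10 at the slowest rate to zero at 390 bpm: fast cycles cannot carry the
  bend's higher harmonics through a band-limited articulatory channel, and
  fast-rate movement shapes are observed to simplify toward ellipses.  A
  rate-independent sharp bend would make the generator's ground truth
  unrecoverable in principle (its harmonics exceed the 25 Hz conditioning
  chain) rather than emulate articulation.
- **Lateral component.** A one-per-cycle sinusoid *in the path geometry*
  (before reparameterization) with RMS 7.5% of the in-plane RMS, so the law
  holds in 3D and the mid-sagittal projection genuinely loses curvature
  information.  Because this lateral motion is smooth and phase-locked, the
  projection penalty it produces is small (fractions of an r² point); real
  tongues, with irregular lateral motion, lose more.
- **Trial framing.** Trials start and end at a principal-axis extremum and
  are framed by 0.3 s resting pads, so each trial contains exactly
  2 × syllables complete movements and filter edge transients fall in the
  pads (junction ringing appears as low-amplitude micro-movements that the
  targeting filter removes, emulating the role of manual selection).
- **Variability and noise.** Per-trial amplitude jitter (sd 5%,
  multiplicative, law-preserving) supplies the within-stratum amplitude
  spread that the A–v* regressions need; head motion is a smooth rigid
  rotation (1.5°) plus translation (2 mm) about a fixed oblique axis at
  0.15 Hz; sensor noise is i.i.d. Gaussian per axis and sample, default
  sd 0.005 mm at 1250 Hz (≈ 1 µm in-band after the conditioning chain).
  The noise default is calibrated so that the emulation reproduces the
  correlation strengths reported for real slow-rate recordings
  (r² ≈ 0.83–0.97): at 0.02–0.05 mm the errors-in-variables dilution from
  noisy curvature at 30 bpm biases the recovered exponent by 0.05–0.10 and
  drives r² to ≈ 0.75–0.88, which no published recording chain exhibits.

What the synthetic tests therefore show: the pipeline recovers known
exponents, gains, delimiters, counts and regime topologies through the full
conditioning chain under realistic noise.  What they do not show: behavior
under cycle-to-cycle shape drift, sensor dropout, palate interaction or
speaker strategy changes — none of which the generator models.

A reproducibility note on the recovered exponent trend: the 25 Hz filter
biases mid-rate exponents downward by up to ≈ 0.03 (its truncation of the
speed profile's harmonics), flattening the 150–210 bpm decrement.  In the
noise-free chain the recovered exponent sequence is still strictly
decreasing across all eight rates; under sensor noise the surviving claim
is the monotone trend (rank correlation ≤ −0.9 and a clear slow–fast
contrast), and that is exactly how the two end-to-end tests are split.

## Phase-space regime score

The occupancy density of the (score, score-velocity) plane is a 2D
histogram over the 1st–99th percentile bounding box (100 × 100 cells,
out-of-box samples clipped onto edge cells so occupancy time is conserved),
smoothed with a Gaussian kernel of one cell and normalized to unit mass.
The regime score is topological: threshold the density at 20% of its
maximum, fill the holes of the resulting high-occupancy set, and report
`area(set) / area(filled set)`.  A ring encloses a hole (score → ~0.12 for
harmonic cycling); dwell blobs do not (score → 1).  Scores ≥ 0.5 classify
as point-like/fixed-point, < 0.5 as ring-like/limit-cycle; a set covering
more than 90% of the grid (e.g. uniform density) is reported indeterminate
at score 0.5.  The score is a quantitative stand-in for what is otherwise a
visual classification; its thresholds are configuration, not claims.

## Problem sizes

Tests and the acceptance script run on deliberately scaled sessions chosen
as the smallest sizes at which every estimate is stable: typically 8 rates ×
2 trials × 15 syllables (acceptance script, ~480 movements, ~2400
speed–curvature pairs) and 3-rate × 6-syllable sessions for unit tests; the
analysis drivers use 8 × 4 × 10.  All randomness flows from explicit seeds;
identical configuration and seed give byte-identical outputs, including the
pipeline's summary JSON.

## Known limitations

- The generator's lateral component is smooth and phase-locked, so the
  3D-over-2D r² advantage it produces is much smaller than in real tissue.
- Within-stratum kinematic variability is a single per-trial amplitude
  scale; real slope scatter (and the slow-rate deviations of the inverse
  duration relation) is richer.
- The A–v* slope at the slowest rate is weakly determined even with four
  trials (tiny amplitude spread against slow-movement peak-speed noise).
- No palate-relative coordinates, no acoustic alignment, no sensor-dropout
  handling, and no dynamical-systems model fitting beyond the critically
  damped gesture.
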