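# Methods

This note documents the models, estimators and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the design decisions taken where the procedure was genuinely
open.

## Conventions

Arena angles are degrees, counter-clockwise positive, y-up; image rows run
downward, so pixel row offsets enter angle computations with a negated
sign, and pixel→mm conversion (12 px/mm) flips y at export.  The stimulus
rotation labels CW/CCW are defined operationally by the mirroring contract:
CW-labelled trials are left unchanged by stimulus alignment and CCW trials
are negated, so that positive angular velocity always means "turning with
the stimulus".  The synthetic walker plants its drives in that
stimulus-relative frame and maps them to the arena frame with the matching
sign (+1 for CW, −1 for CCW), which keeps generator and analysis
self-consistent without asserting a physical rotation sign the hardware
never defined.

## Closed-loop walker (synthetic_data)

Each trial is 5 s static + 5 s motion at 60 Hz in a 27.5 mm-radius arena.
Angular velocity is the sum of three planted components:

* smooth drive — a constant stimulus-relative drive per condition kind,
  switched on at motion onset (gain 1 deg/s per drive unit);
* smooth noise — white noise low-pass filtered at 2 Hz, scaled to
  25 deg/s SD (well below the saccade band);
* saccades — raised-cosine angular-velocity pulses `peak·sin²(πt/D)`,
  peaks 300–600 deg/s, durations 80–200 ms, at Poisson times with
  rejection of overlaps.  The raised cosine concentrates its spectrum near
  1/D, at or near the detector's 10–20 Hz band.

Translation runs at 8 ± 2 mm/s along the heading; the wall is handled by
specular reflection of the heading at a 5 mm buffer, so "near-wall" frames
never occur unless the buffer is disabled, while the reflection's heading
jump is visible to the jump-exclusion stage (hard bounces read as
>1000 deg/s and exclude the trial, as a real jump would).  The ground
truth records the smooth and saccadic series separately; their sum equals
the planted angular velocity bit-exactly, which is the invariant the
decomposition stage is tested against.  Reflection jumps are *not* part of
the planted turning and are listed separately.

Drive table (deg/s smooth drive; syn/anti saccade rates in events/s during
motion):

| mode | condition | smooth | syn | anti |
|---|---|---|---|---|
| linear | unilateral FtB | +12 | 0.20 | 0.05 |
| linear | unilateral BtF | +18 | 0.30 | 0.05 |
| linear | full field | +30 | 0.50 | 0.10 |
| nonlinear | unilateral FtB | −2 | 0 | 1.00 |
| nonlinear | unilateral BtF | +10 | 0.20 | 0.05 |
| nonlinear | full field | +35 | 0.60 | 0.05 |

In linear mode the full-field drive and rates are exactly the sums of the
unilateral ones, making the linear prediction correct in expectation (the
null).  Nonlinear mode mirrors the wild-type phenomenology — unilateral FtB
evokes anti-saccades with almost no smooth turning; full-field rotation
evokes strong smooth syn turning — so the linearity analysis has a positive
control whose error has a known sign.  The magnitudes are declared
assumptions (plausible for walking flies), not measured values; what the
tests establish is the *pipeline's* ability to recover additivity or its
violation, not any quantitative property of real flies.

What the walker does not emulate: body/head articulation, speed–turn
coupling, wall-following behaviour, tracking noise, or any visual-system
dynamics (drives are abstract per-eye signals).  Consequently a passing
linearity null says nothing about real flies' linearity — only that the
estimator is unbiased under an additive agent.

## Tracking

The body is the largest connected component below an intensity threshold
(components under 20 px ignored; border-touching components flagged as
failures).  Position and body axis come from the second-moment ellipse
(scikit-image `regionprops`); a minor/major axis ratio above 0.95 is
flagged as degenerate orientation.  Heading disambiguation crops a
neighbourhood around the body, takes a two-threshold Otsu segmentation
(body = darkest class, wings = intermediate; comparisons are inclusive so
that few-level synthetic images, where the thresholds coincide with class
values, classify correctly) and picks the body-axis direction closer to
the wing-COM→body-COM vector.  Wings trail the body; a `flip` switch
reverses the convention.  On noiseless rendered silhouettes the recovery
errors are ≤0.8° in orientation and <1 px in centroid, with 100% heading
disambiguation over a 360° sweep — an upper bound, since real video adds
shadows, reflections and motion blur that this stage does not model.

## Kinematics and exclusions

Heading is unwrapped before differencing (so 359°→1° reads as +120 deg/s
at 60 Hz, not −21 480).  Speed and angular velocity are backward
differences scaled by the frame rate, then smoothed by a centred rolling
median followed by a centred rolling mean, both 3 frames, with shrinking
edge windows; frames marked invalid are NaN-masked first so spikes cannot
leak through the mean stage.  Jump flags (speed >100 mm/s or
|ω| >1000 deg/s) are computed on the smoothed series.  Trials are excluded
for: any jump frame; any frame within 5 mm of the wall; or mean speed
below 1 mm/s across the whole trial ("inactive" — the threshold is a
package choice, configurable).  Exclusion reasons are prioritised
jump > wall > inactive.

## Saccade detection

The stationary wavelet transform (bior2.6) is shift-invariant, which makes
the band-limited reconstruction usable for event localisation.  The series
is padded symmetrically to a multiple of 2^levels; at 60 Hz the detail
levels with nominal bands intersecting 10–20 Hz are d1 (15–30 Hz) and d2
(7.5–15 Hz); the approximation and all other details are zeroed before
inversion, and the padding stripped.

Band-passing a raised-cosine pulse attenuates it strongly and
width-dependently (measured on this implementation: to ~0.39× of the peak
at 80 ms down to ~0.06× at 200 ms), and the half-peak width of the
reconstruction is a near-constant 25–40 ms reflecting the band's ring
period rather than the event duration.  Amplitude and width criteria on
the reconstruction itself would therefore reject essentially all events.
The detector consequently splits roles:

* the reconstruction supplies *candidates* — local maxima of |r| above a
  2 deg/s floor whose only job is to skip numerically-null wiggles;
* each candidate maps to the nearest raw angular-speed extremum (±125 ms);
* acceptance is decided on the raw excursion: peak speed >200 deg/s, and
  width strictly between 50 and 250 ms, measured between the crossings of
  20% of the peak with sub-frame linear interpolation (at 60 Hz an
  integer-frame width of 3 frames is exactly 50 ms, so interpolation is
  what makes ~80 ms events detectable at all).  The outward walk stops
  early at a local minimum once below half peak, so events riding on
  strong smooth turning do not bleed into it.

Onset/offset are those boundary crossings; displacement is the trapezoidal
integral of the *raw* angular velocity between them (integrating the
reconstruction would inherit the attenuation).  Overlapping events resolve
to the larger peak.  An FFT brick-wall 10–20 Hz band-pass drives the same
candidate logic as an independent oracle; on the planted benchmark the two
backends agree in event count on every trial, and the detector scores
hit rate 1.00, false-discovery 0.00, mean onset error ~19 ms against
planted support starts.

Classification is by the sign of the stimulus-relative displacement (syn
≥ 0, tie to syn); events peaking before motion onset keep the trial's
frame but carry a `pre_motion` flag and are omitted from motion-period
aggregates.  The decomposition sets the saccadic channel equal to the
signal inside event windows and zero elsewhere, so smooth + saccadic
equals the input exactly by construction.

## Path straightness

Walking bouts are inter-saccade intervals (also cut at trial boundaries)
longer than 333 ms with mean speed above 5 mm/s.  For each interior sample
a 333 ms window is centred on it: the chord joins the window's endpoint
samples, and the deviation is the perpendicular distance of the centre
sample ("trajectory midpoint" = the sample nearest the window's temporal
centre) from the chord.  The bout statistic is Σchord/Σdeviation — exactly
2R·sin(L/2R) / R(1−cos(L/2R)) per window on a circle of radius R at
window arc L, the identity the tests pin to 1e-6.  The ratio is unbounded
on straight paths; the denominator is floored at 0.01 mm per window and
the result flagged `is_straight` (the sentinel).  The statistic is
invariant to rigid motions and time reversal and strictly increasing in
circle radius.  Per-point, per-bout and per-trial values are all exported,
since the aggregation level is a reporting choice.

## Linearity analysis

Per fly and condition, the stimulus-relative angular-velocity series of
kept trials are averaged; the prediction for full-field rotation is the
framewise sum of the two unilateral means (built from per-fly condition
means, not trial pairings).  The prediction error is averaged over the 5 s
motion period (the full 10 s variant is a slice argument away), and
smooth/saccadic channel errors are computed the same way — they sum to the
total error framewise.  Group inference: one-sample two-sided t-test of
the per-fly mean errors against zero; Mann–Whitney U (exact enumeration
for combined n ≤ 12 without ties, otherwise normal approximation with tie
correction) for between-group contrasts.  No multiple-comparison
correction is applied.  At study scale (15 flies × 200 trials split over
the three conditions) the additive agent yields |group error| well under
2 deg/s; the across-seed SD of the group mean is ≈0.8 deg/s, so the null
is comfortably but not infinitely far from the 2 deg/s bound.

## Ephys analyses

Baseline: centred rolling mean over 60 s subtracted; records shorter than
the window fall back to global-mean subtraction and are flagged.  The even
window is half a sample off-centre, leaving a slope/(2fs) residual on
drifting records — ~0.2 µV for 1 mV/min at 10 kHz, negligible.

Binning: responses averaged within 16.6 ms stimulus-frame bins; empty bins
are NaN and skipped downstream.  The synthetic scan generator reports
frame onsets on its realised sample grid so binning is exact.

Receptive fields: for each grid point and cardinal direction, the mean
binned response (across repetitions) weights the unit direction vector;
the four are vector-summed.  For a linear cell with local sensitivity F
the cardinal sum Σ_d (F·d)d equals 2F exactly — the reconstruction
identity holds to machine precision and is the factor the normalisation
absorbs.  An optional fixed latency shift (default 0 ms) re-aligns
responses to bar positions.  Grid resolution is 5°×5° over the 140°×80°
screen span.  Metrics: areas at 30%/60% of the maximum vector length,
weighted by cos(elevation) per cell; laterality is reported both as the
contralateral fraction of summed vector magnitudes and as the
resultant-vector fraction, since "total sensitivity" admits both readings.
Screen-deformation remapping is deliberately excluded from the numeric
core.

Spectra: plain periodogram per repetition, averaged, then normalised to
unit total after global-mean subtraction; band fractions over [0, 10] Hz
and (10, 50] Hz (half-open at 10 Hz so the boundary bin counts once).
Flash responses are peak |deviation| from a 200 ms pre-event baseline
within 0.5 s of onset; grating tuning subtracts the 2 s preceding-static
mean from the 2 s motion mean, normalised per cell by the maximum
response.

## Network model

Linear steady state `(I − W + L_g) V = D s`, where `L_g` is the graph
Laplacian of the gap edges scaled by conductance g (current-conserving by
construction: row sums zero).  Inputs are the four per-eye motion signals;
the canonical conditions are CW (left FtB + right BtF), CCW mirrored, and
forward/backward translation (both FtB / both BtF), each with total drive
mass 2.  An optional half-wave-rectified fixed point (tolerance 1e-9,
10⁴ iterations) is available but off by default.

Default weights (all assumptions except the two stated settings): HS ←
ipsi FtB +1, ipsi BtF −1 (opponent), contralateral chemical input 0
(stated); H2 ← ipsi BtF +2.2, contra FtB +0.1 (stated); bIPS ← contra H2
−0.5 (inhibitory); uLPTCrn ← ipsi HS +1 and ipsi bIPS −1; gap edges
HS_L↔H2_R and HS_R↔H2_L.  Two of these choices are load-bearing and
follow from the closed-form solution of the coupled HS/H2 pair
(V₁ = ((1+g)d₁ + g d₂)/(1+2g) and symmetrically):

* **H2's ipsilateral weight (2.2)** exceeds the sum of HS's drive weights
  plus the contralateral weight (2.1).  This keeps the sign of H2's
  forward-vs-backward response difference fixed over g ∈ [0, 1]; below
  that value the difference crosses zero inside the sweep range, the
  translation range OF_tr touches zero, and DI(g) becomes non-monotone.
* **bIPS is inhibitory from H2** (disinhibition of uLPTCrn).  uLPTCrn then
  combines HS and contralateral H2 with the *same* rotation preference
  while their translation components partially cancel, which is what makes
  it the most rotation-selective cell — and what makes silencing either
  HS or H2 chemical output *raise* its DI, the same direction as removing
  the gap junction.  With an excitatory bIPS the combination subtracts,
  and chemical silencing would lower DI instead.

With these defaults DI is monotone non-increasing in g for every cell
(e.g. DI_HS = −g·c / ((1+g)(a+b) + g·q), from 0 at g = 0 to −0.537 at
g = 1), g = 0 reproduces the chemical-only (*shakB*) model exactly, and
responses obey left–right mirror symmetry.  Perturbations: chemical
silencing zeroes a cell class's output columns; `shakB` zeroes g;
`kir_HS` removes both HS chemical outputs and HS gap edges.  The model is
a qualitative tool: weights are not fitted to recordings, there are no
dynamics, and rectifying gap junctions are out of scope.

## Problem sizes and tolerances

Test and acceptance runs use: 50 benchmark trials (plus 100 null trials)
for the detector; 15 flies × 200 trials for the linearity controls; a
29×17-point RF grid at 2 kHz sample rate (the binning is rate-independent;
2 kHz keeps the exact-identity check fast) with 3 repetitions for the
noisy-recovery check; 360 rendered frames at 128 px for tracking; an
11-point g sweep and 1000 random response draws for the network.  Exact
invariants (decomposition conservation, RF identity, g = 0 vs *shakB*,
spectrum normalisation) are asserted at machine precision (≤1e-9);
stochastic recoveries use the margins stated in the tests (hit rate ≥0.90,
cosine similarity ≥0.9, contralateral share ±2 points).

## Known limitations

The generators share none of real data's nuisance structure (tracking
noise, behavioural state changes, arena inhomogeneity, electrode drift
beyond the modelled sinusoid/random walk), so green tests validate the
estimators' correctness and calibration under their stated models, not
field performance.  The detector's raw-excursion width measurement assumes
events are locally unimodal; densely overlapping saccades (<50 ms apart)
merge or resolve to the larger peak.  The straightness sentinel makes the
statistic scale with bout length on perfectly straight synthetic paths —
comparisons should use the `is_straight` flag, not the capped value.  The
network model's DI monotonicity is a property of the shipped default
weights, demonstrated over g ∈ [0, 1], not a theorem for arbitrary
configurations.
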