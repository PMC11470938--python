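# flysteer

Analysis pipeline for bilateral optic-flow course control in freely walking
*Drosophila*: closed-loop optomotor behaviour, wavelet-based saccade
detection, turning decomposition, path straightness, the full-field versus
summed-unilateral linearity test, receptive-field vector-field
reconstruction from intracellular recordings, and a bilateral HS–H2 rate
network with gap-junction coupling.

## The scientific problem

A walking fly stabilises its course with the optomotor response: wide-field
rotation of the visual world evokes turning in the direction of motion.
Rotation presents front-to-back (FtB) motion to one eye and back-to-front
(BtF) motion to the other, so a natural question is whether the binocular
response is just the sum of the two monocular ones.  Presenting each
half-field stimulus alone in a closed-loop arena shows it is not: unilateral
FtB motion evokes rapid body turns *against* the stimulus (anti-saccades),
while full-field rotation evokes smooth syn-directed turning — a nonlinear
binocular interaction attributed to electrical coupling between the
horizontal-system cells (HS) and the contralateral H2 neuron.

This package implements the complete measurement chain needed to quantify
that interaction, and the circuit model used to interpret it:

* **Tracking** — ellipse fit of the fly silhouette plus two-threshold Otsu
  wing segmentation to resolve the 180° heading ambiguity.
* **Kinematics** — rolling-median/rolling-mean smoothing (3 frames),
  jump detection (100 mm/s, 1000 deg/s), wall (5 mm) and inactivity
  exclusions, and mirroring of CCW trials into a stimulus-relative frame.
* **Saccades** — stationary wavelet transform (bior2.6), 10–20 Hz band
  isolation; candidate peaks on the reconstruction, with the 200 deg/s
  amplitude threshold and the 50–250 ms width bound evaluated on the raw
  angular-velocity excursion.  Turning is decomposed exactly into smooth
  and saccadic components.
* **Path straightness** — inter-saccade walking bouts (>333 ms, >5 mm/s);
  per-window chord / perpendicular-deviation ratio.
* **Linearity** — prediction `full ≈ FtB + BtF` from per-fly condition
  means, per-fly mean prediction error over the motion period, one-sample
  two-sided t-test; two-sided Mann–Whitney U for group comparisons.
* **Ephys** — 60 s rolling-baseline subtraction, 16.6 ms frame binning,
  scanning-bar receptive-field reconstruction (vector sum over the four
  cardinal directions; for a linear cell the recovered vector is exactly
  2× the local sensitivity), RF size/laterality metrics, flash and grating
  tuning, and unit-normalised power spectra with 0–10 Hz / 11–50 Hz band
  fractions.
* **Network model** — eight-cell linear rate network (HS, H2, bIPS,
  uLPTCrn × two hemispheres) with ohmic gap junctions between HS and the
  contralateral H2, solved at steady state for the four canonical flow
  conditions, summarised by the Discrimination Index

  `DI = (OF_translation − OF_rotation) / (|OF_translation| + |OF_rotation|)`

  where each `OF` term is the max−min response range over the condition
  pair (DI = +1: purely translation-selective; −1: purely
  rotation-selective).

A `synthetic_data` module generates every input with planted ground truth —
closed-loop walking with Poisson saccade pulses, silhouette frames,
scanning-bar voltages from a planted vector field, and baseline traces with
controlled spectral content — so every stage is validated end to end.

## Worked example

```python
import numpy as np
from flysteer import saccades, synthetic_data, netmodel

[(omega, truth)] = synthetic_data.make_detector_benchmark(1, seed=8)
events = saccades.detect_saccades(omega, fs=60.0)
print(f"planted {len(truth)} saccades, detected {len(events)}")
for e in events[:3]:
    print(f"  t={e.peak_frame/60:5.2f} s  peak={e.peak_speed:6.1f} deg/s  "
          f"width={(e.offset_time_s-e.onset_time_s)*1000:5.1f} ms  "
          f"displacement={e.displacement_deg:+6.1f} deg")

decomp = saccades.decompose_turning(omega, events, fs=60.0)
print(f"mean smooth {decomp.mean_smooth:+.1f} deg/s, "
      f"mean saccadic {decomp.mean_saccadic:+.1f} deg/s")

sweep = netmodel.di_vs_g_sweep(netmodel.default_config(), np.array([0.0, 0.5, 1.0]))
print(sweep[["g", "HS_L", "H2_L", "uLPTCrn_L"]].round(3).to_string(index=False))
```

prints

```
planted 11 saccades, detected 11
  t= 0.35 s  peak= 525.9 deg/s  width= 79.3 ms  displacement= +25.8 deg
  t= 1.57 s  peak= 402.7 deg/s  width= 77.9 ms  displacement= +17.0 deg
  t= 2.22 s  peak= 446.8 deg/s  width= 76.2 ms  displacement= -17.8 deg
mean smooth +0.8 deg/s, mean saccadic +11.9 deg/s
  g   HS_L   H2_L  uLPTCrn_L
0.0  0.000 -0.045     -0.537
0.5 -0.361 -0.348     -0.759
1.0 -0.537 -0.500     -0.846
```

The detector recovers all eleven planted saccades with their signs and
widths; the decomposition shows the trial's net turning is carried almost
entirely by saccades.  In the network sweep, raising the HS↔H2 gap
conductance `g` drives the DI of every cell downward — stronger electrical
coupling makes the whole circuit more rotation-selective, and silencing
either cell's chemical output (or the gap junction itself, the *shakB*
condition) moves it back toward translation.

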