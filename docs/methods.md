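# Methods

## Scope and model structure

The package simulates chromosome congression in a large oocyte nucleus
and re-implements the accompanying trajectory and image analyses. The
simulation world is a sphere of 70 µm diameter; time zero is NEBD and
the default run covers 25 simulated minutes at a 0.05-s step. Three
nested model variants are exposed:

1. **Search-and-capture** — dynamically unstable astral microtubules
   explore the nucleus from two static centrosomes; chromosomes diffuse
   in place. Emulates acute actin depolymerization (Latrunculin).
2. **+ velocity field** — the contractile F-actin network is not
   represented by explicit filaments; its effect on free chromosomes is
   the field v(x,t) = (p − x)/(t_x − t) for t ≤ t_m (t_x = 15 min,
   t_m = 12.5 min), zero afterwards. Each chromosome moves toward the
   convergence point *p* at a speed constant in time and proportional to
   its initial distance; all would meet *p* at t_x if transport did not
   stop at t_m. The field acts only on free chromosomes.
3. **+ binding gate** — kinetochore binding is blocked for the first
   4 min after NEBD, then stepped to 10, 30, 70 and 100% of the maximal
   rate at minutes 4, 5, 6 and 7 (right-continuous, piecewise
   constant), mirroring the disassembly kinetics of the F-actin patches
   that enclose chromosomes. An alternative convention with increments
   at minutes 5–8 is selectable (`GateSchedule.ramp(5)`).

## Geometry

The AP point *p* lies on the nuclear boundary on the outward ray through
the centrosome midpoint. Both centrosomes sit exactly 3 µm inside the
boundary (|c − center| = R − 3) and 6 µm apart, symmetric about the
center→p axis; their exact azimuthal orientation is immaterial to any
reported statistic. This puts each centrosome 4.34 µm from *p*. Initial
chromosome positions are uniform over the nuclear volume, at least 1 µm
inside the boundary and 2 µm apart pairwise; there are no
excluded-volume interactions afterwards.

## Microtubules

Filaments are straight (rotation neglected), nucleated with uniformly
random directions, and never rescued: a shrinking filament retracts to
zero length and immediately renucleates in a fresh random direction.
Tips touching the cortex undergo catastrophe immediately. The stochastic
catastrophe rate is hinged-linear in length,

    k_cat(L) = k0 + k1 · max(0, L − L_c),

a monotone form chosen over a plain linear law after calibration showed
the linear form cannot produce both roughly distance-uniform capture
kinetics inside the search range and a sharp ~30 µm cutoff: with
k0 + k1·L the capture time rises ~14-fold between 15 and 25 µm while
rare long excursions still capture chromosomes beyond 37 µm. The hinge
separates the two requirements — k0 sets the search flux inside the
range, the knee sets the range. The plain linear law remains available
as the L_c = 0 case, and the rate function is a single point of change
for other monotone forms.

Asters start from zero length at NEBD: before envelope breakdown the
nuclear volume is inaccessible to cytoplasmic microtubules, so the
filaments invade it only from t = 0. This growth delay (~1–2 min to
reach mid-range targets) is part of the model; a pre-equilibration
period is available via `mt_burn_in` for users who prefer a stationary
aster at t = 0.

## Chromosome motion and capture

Free chromosomes follow Euler–Maruyama integration of the velocity field
plus Brownian motion of a 0.8-µm sphere in 0.1 Pa·s fluid at 293 K
(D = kT/6πηr ≈ 2.68·10⁻³ µm²/s; 293 K matches the 19–21 °C at which
these oocytes are imaged).
Brownian excursions reflect radially at the nuclear boundary.

A capture candidate is any filament whose segment passes within
ρ_c + r_chromosome of the chromosome center (lateral attachment over the
whole chromosome surface; no discrete binding sites). Each candidate is
tried nearest-first with per-step success probability
1 − exp(−k_on·g(t)·dt). On success the chromosome jumps to the nearest
point of the filament and is transported poleward at the dynein speed
v_dyn = 9.22 µm/min; Brownian noise is off during transport (directed
transport dominates experimentally). If the filament tip shrinks past
the attachment point the attachment slides with the tip; if the filament
fully depolymerizes the chromosome is released to the free state.
Arrival is reaching `arrival_radius` (2 µm) of the centrosome. Free
chromosomes at the end of a run are scored lost.

## Parameters and calibration

Fixed by the study conditions: dt = 0.05 s, t_end = 25 min, t_x = 15,
t_m = 12.5, 22 chromosomes of radius 0.8 µm, viscosity 0.1 Pa·s,
v_dyn = 9.22 µm/min, the gate schedule, and the 3-s trajectory sampling
interval.

The free microtubule parameters (v_g, v_s, filament number, k0, k1, L_c,
ρ_c, k_on) are not published. They were calibrated **once**, on model
variant 1 only, against the two Latrunculin-condition observables — mean
capture time of chromosomes starting within 30 µm of the AP
(6.16 ± 3.92 min) and the ~30 µm capture range — and then frozen for all
variants. Frozen values:

| parameter | value | units | role |
|---|---|---|---|
| v_g | 15 | µm/min | growth speed |
| v_s | 25 | µm/min | shrinkage speed |
| n_mt_per_aster | 150 | — | search flux |
| k0 | 0.4 | 1/min | basal catastrophe (flux inside range) |
| k1 | 2.0 | 1/(min·µm) | catastrophe slope beyond the knee |
| L_c | 20 | µm | knee length (sets the ~30 µm range) |
| ρ_c | 0.8 | µm | capture radius around the filament |
| k_on | 0.02 | 1/s | maximal kinetochore binding rate |

k_on is the only knob that delays captures near the asters without
extending the range; its calibrated value makes binding, not encounter,
rate-limiting at short range. Capture-range statistics are measured as
distance to *p*, while the search kinetics are governed by distance to
the centrosomes (~4 µm deeper) and blurred by ~5 µm of Brownian
displacement over 25 min; both effects are absorbed by the calibration.
With these values frozen, variants 2 and 3 reproduce full capture of all
22 chromosomes and a ~9.2-min mean capture time without further tuning.

## Trajectory analysis

Capture events are the transition from slow advective/diffusive motion
to fast directed poleward transport. A step (3-s frame displacement)
qualifies when its speed is ≥ 5 µm/min, the angle to the previous step
is ≤ 60°, and the distance to *p* decreases. An event needs four
consecutive qualifying steps, or two when a reversal of the smoothed
(5-frame) overall direction coincides. Two refinements make the rules
robust to localization noise at this frame rate:

- **Net-motion confirmation.** The run as a whole (up to 12 frames,
  truncated at the pole) must be fast and poleward, and clearly faster
  than the track's own pre-phase (≥ 1.5× the median pre-event windowed
  speed). Per-step apparent speeds are strongly inflated by
  frame-to-frame noise (a stationary point with 0.1 µm/axis jitter
  "moves" at ~5 µm/min), and the advective phase of distal chromosomes
  approaches the absolute threshold on its own; independent noise
  cancels in the net displacement, so this check removes both
  false-positive classes while leaving genuine transport untouched.
- **Change-point refinement.** The confirming run can start a few frames
  into transport when noise breaks the angle criterion; the reported
  event time is the least-squares two-segment breakpoint of the
  distance-to-AP series within ±16 frames of the run start, which
  localizes the knee to about one frame.

Phase speeds are medians of 5-frame window speeds (robust to edge
contamination and unbiased by localization noise, unlike per-step
speeds) on each side of the event; frames in the arrival plateau
(windowed speed < 1 µm/min within 8 µm of the AP — wide enough to cover
arrival at either centrosome) are excluded. Thresholds live in
`DetectionThresholds` and are config-exposed.

Detector performance is assessed on the labeled synthetic suite.
A track counts as a detectable positive when its drawn transport speed
is at least the fast threshold and at least seven transport frames occur
before the arrival zone — tracks switching essentially at the pole, or
slower than the definition of "fast", do not contain the phenomenon the
rules define. On that suite recall is ≥ 0.9 with a false-positive rate
≤ 5% on transport-free tracks, and the median event-time error is under
one frame. Because detection requires fast motion, the mean post-event
speed over detected events sits slightly above the generator mean
(≈ 9.6 vs 9.22 µm/min, the mean of the speed distribution above the
5 µm/min threshold); the same selection operates in the manual analysis
the thresholds mirror.

## Patch quantification

Patch intensity is the sum of voxel values whose centers lie inside a
2.5-µm-radius sphere around the chromosome center (the "5-µm diameter
sphere"); voxels outside the image are excluded and the covered fraction
reported. Traces are normalized to the mean pre-NEBD level. Timings use
a detection band of 1 + ε (ε = 0.2) with 3-sample persistence: assembly
onset is the first sustained crossing after NEBD, the peak is the argmax
of a 5-sample moving average, and disassembly is the first sustained
post-peak return into the band. A trace that never leaves the band
reports no patch.

## Synthetic data

The generators produce the statistical structure the analyses assume,
with ground truth:

- **Trajectories**: phase 1 is exact per-frame advection (control) or
  pure diffusion (Latrunculin) plus Brownian noise; at the drawn switch
  time (control 9.21 ± 2.36 min; Latrunculin 6.16 ± 3.92 min, only for
  chromosomes within 30 µm — distal ones are lost) the track moves
  straight to *p* at the drawn speed (9.22 ± 2.86 µm/min, truncated
  positive) until 2 µm away, then rests; 0.1 µm/axis frame jitter
  emulates localization noise.
- **Intensity traces**: flat at 1 before NEBD, linear rise, cosine fall,
  scaled by a random background and 2–6× amplitude, with 5%
  multiplicative noise. The template is parameterized by its observable
  times — the band-crossing onset, the peak, and the band-crossing
  return — so the drawn timings are exactly what an unbiased estimator
  should recover regardless of amplitude; the trace then relaxes fully
  to baseline shortly after the return time.
- **Image stacks**: chromosomes and patches as 3D Gaussian blobs over a
  uniform background with optional Poisson noise; the patch blob is
  scaled by the analytic in-ROI Gaussian mass so the spherical-ROI sum
  reproduces the template, and positions are emitted as ground truth.

The generators emulate frame rate, noise level, two-phase kinetics and
loss structure, not microscopy physics: no point-spread function beyond
the Gaussian blob, no bleaching, drift, segmentation error or tracking
gaps. Passing recovery tests therefore demonstrates correctness of the
analysis logic under the stated noise model, not robustness to every
artifact of real recordings.

## Numerical and reproducibility notes

- Euler(–Maruyama) at the global 0.05-s step throughout; the advective
  ODE is integrated to ≤ 0.1 µm error over the full transport phase.
- All randomness flows from one seed through four named substreams
  (placement, microtubules, transport, capture); equal seeds give
  bit-identical results on one build. Cohorts use seeds base + i.
- The microtubule step consumes draws in a documented order (one uniform
  per filament, then normals per renucleated filament in index order),
  verified bit-identically against a per-filament reference loop.
- Chord lengths to the boundary are cached per filament and recomputed
  only on renucleation. Capture distance checks are skipped for
  chromosomes beyond each aster's current reach (a pure performance
  filter). Once every chromosome has arrived, remaining frames are
  static and the stepper exits early.
- Default problem sizes for cohort-level statistics are 13 oocytes ×
  22 chromosomes, 100 traces for patch-timing recovery, and 200
  replicates for detector benchmarks.

## Known limitations

- No explicit F-actin filaments or network mechanics; the velocity field
  is prescribed, not emergent, and the patch is a binding-rate gate, not
  a structure.
- No end-on attachment conversion, biorientation or spindle assembly;
  the model ends at poleward delivery.
- The catastrophe law and all free microtubule parameters are a
  calibrated surrogate for unpublished values; other (k0, k1, L_c, k_on)
  combinations reproducing the same two calibration observables are not
  excluded.
- Chromosome placement treats chromosomes as points after placement;
  crowding near the AP late in congression is not modeled.
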