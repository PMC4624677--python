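# Methods

## Locomotor model and preset calibration

A larval session is a two-state alternating renewal process. The larva is
either *still* (zero displacement, resting at the bottom of the well) or in a
*swim bout*. Segment durations are a refractory minimum plus a geometric
tail, at frame resolution:

* bout duration: minimum 0.2 s (a bout is at least a few tail beats), mean
  `bout_duration_mean` (default 1 s);
* inter-bout interval: minimum 0.4 s, with its mean set so that bout onsets
  occur at `bout_rate` per session minute.

The refractory minima keep bout episodes well separated at frame resolution,
so a threshold-crossing bout detector recovers the generating episode count
exactly on noiseless data; without them, a geometric tail alone would place
a non-negligible mass of bouts below any practical minimum-duration filter
and of gaps below any practical merge window, making the generator's own
bout count ill-defined for a detector.

During a bout the larva performs a correlated random walk: per-frame speed
is N(`speed_mean`, `speed_sd`) clipped at 0 (mm/s), heading diffuses with
standard deviation `turn_sd` (default 0.6 rad) per frame and resets uniformly
at each bout onset. A per-bout target depth is drawn in the upper half of the
water column with probability `top_half_bias`; up to 60% of each step's
length budget moves the larva vertically toward that target and the
remainder is horizontal, so the 3-D step length equals speed × Δt exactly.
Walls are specular: unconstrained coordinates are mirror-folded into the
well (11 mm square, 15 mm water column, one well of a 48-well plate).
Frame rate defaults to 25 fps and sessions to 30 min.

Folding shortens the recorded polyline slightly wherever a step crosses a
wall (~1-2% at hyperactive speeds in an 11 mm well), and frame quantisation
and session-edge truncation bias the onset count by a fraction of a percent.
The hyperactive preset (`ptz20`) is therefore calibrated by a one-step
Monte-Carlo correction (`synth.calibrate_locomotor_preset`): starting from
the analytic guesses (onset rate = target count per session minute; speed =
target distance / expected moving time), the realized ground-truth means
over 2000 internally-seeded sessions set a multiplicative correction. The
frozen constants target 832.7 bouts and 931.4 cm per 30-min session; the
control preset (0.2 bouts/min, 2 mm/s) swims ~1 cm per session, well under
the 10 cm bound for untreated larvae. VPA presets interpolate bout rate,
speed and top-half bias linearly from `ptz20` toward `control` at rescue
fractions 0.1/0.45/0.8/1.0 for 0.25/0.5/0.75/1.0 mmol/L, reproducing a
graded, saturating dose-response.

What the generator does *not* emulate: between-animal variability (the
screen's reported per-animal SDs are several-fold larger than the
within-session sampling noise simulated here, so simulated group tests are
better-powered than real ones), burst-and-glide microstructure within bouts,
multi-animal occlusion, and background clutter in the videos. Passing tests
therefore demonstrate correctness of the measurement chain, not robustness
to all real-world imaging conditions.

## Rendering and tracking

Videos are dark Gaussian blobs (σ = blob_radius/1.5, default radius 4 px,
optionally elongated along the heading) on a light background (235 vs
minimum 40 gray levels), with optional additive Gaussian pixel noise and
1-Hz illumination flicker. The well is centred in the image at 8 px/mm.

The tracker thresholds |frame_t − frame_{t−1}| at `diff_threshold` (default
10 gray levels), cleans the mask with morphological opening/closing (disk
radius 1) and takes the largest connected component of area ≥ 9 px². Pixel
coordinates are 0-based, origin top-left; conversion to well mm flips the
vertical image axis. Because the difference mask spans both the old and new
blob footprints, its centroid lags the animal by half a step; the tracker
therefore refines each motion-gated candidate with a darkness-weighted
centroid of the current frame inside the detected region (detection stays
purely differential; only sub-pixel localisation uses intensities). This
puts the mean localisation error near 0.15 px on noiseless video. Frames
without an accepted detection carry the previous position forward
(`detected=False`) — interpolation would fabricate distance during
stillness, where differencing genuinely observes nothing. Detections
implying more than `max_jump` (50 mm) per frame interval are rejected as
implausible. The first accepted detection back-fills earlier frames, and a
sequence with no motion at all raises an error. 3-D fusion averages the
shared x axis of a top and a side view; frames disagreeing in x by more
than `x_tolerance` (1 mm) are flagged and linearly interpolated.

## Behavioural endpoints

Per-frame speed is the finite-difference displacement over Δt, smoothed by a
centred boxcar (5 frames). A movement bout is a maximal run of smoothed
speed above 2 mm/s, after merging runs separated by less than 0.2 s and
dropping runs shorter than 0.12 s. These defaults, together with the
generator's refractory minima, close the calibration loop: the detector
applied to simulated hyperactive sessions reproduces the preset's target
bout count to well within 10%. "Instances of movement" is thus a declared
operational convention (discrete bouts, not per-frame motion events).

Path length sums inter-frame displacements, ignoring steps below a noise
floor (0.1 mm, ~0.8 px) so sub-pixel jitter cannot accumulate; distances are
reported in cm. Top-half occupancy is the fraction of frames with the
vertical coordinate above half the water column; occupancy trace maps
histogram positions on a well-aligned grid, conserving the sample count.

## Rescue analysis

Rescue fractions are computed per metric (bout count and distance are never
pooled) from group means and clamped to [0, 1]. The Hill fit uses
Levenberg-Marquardt least squares with EC50 parameterised on a log scale.
Group comparisons default to the two-sided Mann-Whitney U test (locomotor
metrics are heavy-tailed); ties are mid-ranked without continuity
correction, so identical samples give p = 1 exactly, and Welch's t-test is
available by flag. No multiplicity correction is applied by default (the
screen reports per-panel comparisons); Holm-adjusted p-values are available
via `rescue.holm_correction`.

## Aspiration model

The supplementary material describing the original rig's mechanical model is
not available, so the module adopts the standard elastic half-space
aspiration model consistent with a linear P-L relation: E = 3Φ·R_p·s/(2π)
with slope s = dP/dL, shape factor Φ = 2.1 and incompressibility ν = 0.5,
giving G = Φ·R_p·s/(2π). Both constants are arguments; the defaults
R_p = 25 µm and a 10-step pressure ramp are placeholders for unreported
protocol values and are flagged as configuration in CLI output. A fit with
r² < 0.98 is reported as non-linear and refused for modulus estimation
rather than silently converted.

Force traces are modelled as a saturating exponential F(t) = 1 − e^{−t/τ}
sampled at 1 ms over 12τ; preset τ values are back-solved from the reported
times-to-peak via t_peak = τ·ln(100) at the q = 0.99 criterion (52.1 ms for
240 ms control, 38.4/32.4 ms for the PTZ arms). Preset moduli (0.5 MPa
control, 0.75 MPa for every PTZ concentration) are chosen at a plausible
chorion scale; only their ordering and equality across PTZ doses carry
meaning. Force units are arbitrary and all force analysis is
scale-invariant.

Known limitation: on a saturating trace the q = 0.99 criterion sits where
the curve is nearly flat, so measurement noise of fractional sd ε shifts
the crossing by ≈ 100·τ·ε — the peak time should be read from
trial-averaged traces (the examples do), and the simulated recovery
criteria use noiseless traces for exactly this reason. Viscoelastic creep
models and the pipette-contact mechanics are out of scope.

## Cohort model and outcome statistics

Each embryo carries one death threshold and one hatch threshold (uniform on
[0, 1]). Cumulative marginal probabilities per scored day (3 and 5 dpf) give
death by threshold on the death probability and hatching by threshold on
the conditional-on-alive probability, so the marginal hatched fraction of
all treated embryos is exact. Death precludes hatching within a day's
accounting (hatched + dead ≤ treated per row); an embryo hatched at day 3
that dies by day 5 moves to the dead tally. Unfertilised eggs are treated as
day-0 deaths. The reported control means (87.1% hatched, ~13% dead at
5 dpf) sum to just over 100%, which exclusive accounting cannot represent;
the control preset uses 12.9% day-5 mortality. The 20 mmol/L arm's hatch
rates are not reported numerically, only as not significantly different
from control; its preset (75%/78%) is the largest compatible with exclusive
accounting given its reported mortality.

Rates are unweighted means of replicate proportions ×100 with
SEM = sd/√k across replicates (k = 1 yields SEM 0 with a flag). Hatching
denominators include all treated embryos by default (`alive_denominator`
restricts to survivors). Treatment effects use the two-sided conditional
Fisher exact test on replicate-pooled 2×2 tables — group sizes of tens make
the exact test preferable to a normal-approximation z-test — with a mid-p
variant by flag. "n = 30" is read as embryos per replicate, with 3
replicates per simulated cohort by default.

## Numerical conventions

* All randomness flows from one integer seed through named, counter-based
  sub-streams (`zfscreen._rng.substream`); identical seeds give bit-identical
  outputs, and sub-streams are reproducible in isolation.
* Problem sizes in the test and acceptance suites: 20 noiseless 30-s clips
  for tracker fidelity, 200 sessions per preset for calibration closure, 100
  simulated screens (6 arms × 30 animals) for dose-response properties, 200
  simulated cohorts/seeds for the power and type-I checks, 100 seeds for
  noisy modulus recovery, 1000 random 2×2 tables for the exact-test check.
* Degenerate inputs fail loudly: constant tongue lengths (rank-deficient P-L
  fit), all-zero force traces, all-equal rescue fractions, equal
  control/PTZ baselines, zero-variance Welch comparisons, cohort rows
  violating count conservation.
* Boxcar smoothing uses plain convolution for speeds ('same' mode; edges are
  attenuated) and a truncated-window average for force traces (edges use
  shorter one-sided windows so the plateau level is unbiased).
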