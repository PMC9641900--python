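# Methods

`cervimotion` measures cervical **sagittal intervertebral rotational motion
(SIRM)** — the change of the angle between adjacent vertebral midplanes
across postures — from 22 vertebral-corner landmarks annotated on flexion,
neutral and extension lateral views.  This note documents the measurement
model, the synthetic study conditions, the detector, the statistics, and
the numerical choices, in that order.

## Landmark scheme and coordinate conventions

Each typical vertebra C3–C7 contributes its four body corners (G1
anterior–superior, G2 posterior–superior, G3 anterior–inferior, G4
posterior–inferior); C2, whose body shape is atypical, contributes only its
two inferior corners (B3 anterior, B4 posterior): 22 landmarks per view.
Ids are `"<level>-<code>"` strings (`"2-B3"`, `"4-G1"`, …) with a fixed
channel order (C2 first, then C3–C7) used everywhere arrays appear.

Coordinates are 0-based pixels, origin top-left, x rightward, y downward.
All geometry converts to a metric y-up frame (x·spacing, −y·spacing) before
any trigonometry.  Because lateral radiographs may face either way and
angle *signs* depend on orientation, every view is normalized to "patient
faces +x" before measurement: if the mean x of the anterior-role landmarks
is below that of the posterior-role landmarks, the view is x-mirrored about
the image width.  The operation is idempotent, and a view and its mirror
measure identically.  Facing normalization is an artifact-level choice —
radiograph facing is not a property the measurement should depend on.

## Midplanes and SIRM

The midplane of a typical vertebra is the line through the midpoint of its
anterior corners, mid(G1, G3), and the midpoint of its posterior corners,
mid(G2, G4).  This is the geometric-midplanes construction: the line
approximates the body's long (antero-posterior) axis, the correct axis for
sagittal rotation.  (Averaging superior/inferior edge midpoints instead
would track the wrong axis.)  For C2 the line through B3 and B4 stands in.

For each view, the segmental angle of Cn/Cn+1 is

θ = wrap(angle(midplane Cn) − angle(midplane Cn+1)),

with angles taken by two-argument arctangent of the anterior→posterior
vector in the y-up frame and wrapped to (−180°, 180°] (ties at ±180 map to
+180).  On facing-standardized views, positive θ means the cranial vertebra
is relatively extended.  SIRM is the signed across-posture difference,
ordered so the later posture in the pair name (E > N > F) is the minuend:

SIRM(F/N) = θ_N − θ_F, SIRM(N/E) = θ_E − θ_N, SIRM(F/E) = SIRM(F/N) + SIRM(N/E).

Keeping SIRM signed (rather than taking magnitudes) preserves the exact
additivity F/E = F/N + N/E, which published per-segment means also satisfy
(e.g. C4/5: 7.05 + 5.76 ≈ 12.81 ≈ the F/E mean).  F/E is *computed* as the
sum of the other two pairs so the identity holds bit-exactly in floating
point; at cervical angle magnitudes the wrap can never be triggered by this
choice.  Whether reported mean differences are model − reference or the
reverse is ambiguous in published tables; this package fixes
model − reference everywhere.

Invariances (all tested): rigid transforms and uniform scaling of a view
change no angle by more than 1e−9°; mirroring changes nothing after facing
standardization; landmarks built by the generator with prescribed rotations
measure back to those rotations within 1e−9°.

## Synthetic study conditions

The generator emulates the three-posture annotation sets of a clinical
cohort; every downstream module is testable against its known ground truth.

**Skeleton.** Vertebral bodies are rigid rectangles, default 16 mm wide
(antero-posterior) × 13 mm high, stacked caudal→cranial with a 5 mm
inter-body gap; C2 is its inferior edge only.  These are plausible adult
cervical dimensions, config-exposed, with no provenance claim.  The chain
is posed by rotating each cranial vertebra about the midpoint of the gap
below it; since only angles are measured, any rotation center consistent
with rigid vertebrae yields the same SIRM.

**Postures.** Neutral gives every segment a baseline 2° lordosis.  Flexion
subtracts the segment's F/N rotation, extension adds its N/E rotation, so a
case is internally consistent by construction and SIRM round-trips exactly.
Per-segment (mean, SD) defaults for F/N — C2/3 3.87±2.19, C3/4 6.24±3.49,
C4/5 7.05±3.69, C5/6 7.50±4.08, C6/7 7.79±4.01 — and N/E — 2.87±1.74,
4.73±3.47, 5.76±3.84, 4.43±2.93, 2.70±1.90 (degrees) — are the
reference-standard values reported for a 100-case adult clinical test set;
draws are independent normals.

**Annotation noise.** Noise is isotropic Gaussian per landmark.  The
calibration target is the reported inter-observer reliability: ~97.5% of
*pairwise* annotator–annotator landmark distances within 2 mm.  Inverting
the Rayleigh CDF, 1 − exp(−r²/2σ²) = 0.975 at r = 2 mm gives σ ≈ 0.74 mm
for the pairwise displacement; each individual simulated annotator
therefore deviates from the consensus by σ/√2 ≈ 0.52 mm per axis
(`NoiseModel.annotator_sigma_mm`).  `perturb_annotations` itself takes the
literal per-axis SD of the perturbation being applied.  The Gaussian model
is an assumption — only threshold percentages, not an error distribution,
are available to calibrate against — and it reproduces the 2 mm level by
construction while being somewhat wider than observed at the 1 mm level.

A known limitation follows from the geometry: independent landmark noise of
0.52 mm on a 16 mm body propagates to ≈ 2.6° of segmental-angle noise per
view and ≈ 3.7° of single-annotator SIRM noise, larger than the ≈ 2°
differences observed between real raters, whose errors are presumably
correlated along vertebral edges.  Consequently the simulated
*single-annotator vs truth* error overstates clinical disagreement, while
the *reference standard* (mean of three simulated annotators) vs ground
truth gives SIRM MAE ≈ 1.7°, inside the 1.2–1.7° clinical band — that is
the comparison the package's sanity tests use.  Passing those tests shows
the pipeline's statistics behave correctly under calibrated noise, not that
the renderer reproduces clinical image difficulty.

**Rendering.** Views render as filled body quadrilaterals (plus a C2
wedge) at bone intensity over a cranio-caudal background gradient,
Gaussian-blurred (σ 1 px) with additive pixel noise; ground-truth
landmarks are exactly the polygon corners.  Default canvas 128×128 px at
1.0 mm/px — a full cervical spine in frame at desk scale.  Not emulated:
soft-tissue texture, osteophytes/fusions, projection effects, exposure
variation; detector results on these renders do not predict clinical PCK.

## Landmark detector

A heatmap-regression detector at desk (CPU) scale: the network regresses
22 Gaussian-bump heatmaps (peak 1.0, SD 2 cells) at stride 4 from a
128×128 input; each channel's argmax (first row-major cell on ties) is the
prediction, mapped back to the original frame through the recorded affine.
The trunk keeps a high-resolution stream (1/4 scale after a two-conv stem)
alongside a half-resolution stream of doubled width and fuses the two in
both directions at every stage — the parallel-branch multi-resolution idea
used by high-resolution keypoint networks, reduced to 2 branches × 2
stages, width 16.  It is implemented directly in numpy (im2col
convolutions, manual backprop); training is single-threaded and exactly
reproducible from the seed.

Training minimizes mean-squared error between predicted and target
heatmaps with SGD (momentum 0.9) for 90 epochs, batch 8, keeping the
checkpoint with the lowest validation loss.  Desk-scale choices that
depart from a full-scale GPU recipe, all config-exposed:

- **learning rate 1.5 with cosine decay** — a from-scratch toy network
  needs desk-scale rates; with the loss averaged over all heatmap cells,
  gradients are tiny and rates near 1e−6 leave the network at its
  zero-output baseline;
- **weight decay 1e−4** — at desk learning rates a 5e−4 decay visibly
  over-shrinks weights and blurs heatmap peaks (held-out PCK@4px drops
  from ~89% to ~66%);
- **coordinate channels** — normalized x/y planes appended to the input
  give the small-receptive-field trunk the global position cue needed to
  tell apart same-role corners of adjacent vertebrae, whose local
  appearance is identical;
- **near-zero head initialization** — the initial output starts at the
  empty-heatmap baseline, stabilizing early steps;
- **horizontal flip off** — flipping a lateral view swaps
  anterior/posterior semantics; facing standardization plus flip-off
  avoids relabeling ambiguity.  Rotation ±8° and scale 0.9–1.1
  augmentation stay on.

Decoding is plain argmax; a channel with no positive activation is flagged
(coordinates still returned, confidence 0) rather than raised.  No
sub-pixel refinement by default.  At stride 4 the quantization bound is
√2·2 ≈ 2.8 px, so the 4 px PCK radius used by the desk acceptance check is
reachable by a correctly-peaked model.  Typical desk results (200 train /
50 val / 50 test renders, one CPU, ~2 min): held-out PCK@4px ≈ 85–90%,
median error ≈ 2.3 px; a single image overfits (constant learning rate)
to ≈ 6–10% of the empty-heatmap baseline loss within 200 epochs.  The clinical figures reported for the full-scale
system (94–100% PCK at 2 mm on radiographs) are out of reach at desk scale
by design and are not targets of this package's tests.

## Evaluation battery

All statistics operate on vectors aligned case-by-case; differences are
model − reference.

- **Reliability**: Euclidean landmark distances in mm (pixels × spacing),
  reported as percentages within 1/2/3 mm.  Threshold comparisons use ≤,
  so boundary cases count as within.
- **PCK / MPCK**: percentage of predictions within an r-mm radius of the
  reference (radius converted to pixels via spacing).  Per-landmark PCK
  pools all cases first; MPCK averages each vertebra's landmark PCKs
  (2 for C2, 4 for C3–C7).
- **Reference standard**: the coordinate-wise (or value-wise) arithmetic
  mean over annotators.
- **Agreement**: mean difference; SD of differences (n−1); MAE and RMSE by
  their usual formulas; Bland–Altman 95% limits of agreement
  mean ± 1.96·SD; Pearson r with Fisher-z CI; paired two-sided t-test.
  ICC is **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures — the standard form for method comparison, with the
  McGraw–Wong F-based CI (verified against an independent
  variance-components oracle and against `pingouin`).  The RMSE summary
  identity RMSE² = d̄² + s²(n−1)/n links the panel to published summary
  rows.
- **MAE/RMSE CIs**: seeded nonparametric bootstrap, 2,000 resamples,
  percentile interval — distribution-free and reproducible; no method for
  these CIs is standard enough to assume.
- **Rater comparison**: for each rater, the absolute deviation from the
  mean of the other two raters, versus the model's deviation from the same
  baseline, compared by paired t-test.
- Degenerate inputs are flagged, not silently NaN: identical vectors →
  `perfect_agreement` (r = ICC = 1, t = 0, p = 1); zero variance →
  `zero_variance`; identical paired differences → `degenerate_pairs`
  (p = 1).  p-values are raw, two-sided, α = 0.05, no multiplicity
  correction.

## Numerical and I/O choices

- Angle wrap (−180, 180], tie → +180; arctangent on mm-scaled coordinates
  (anisotropy-safe should spacing ever differ by axis).
- Midplanes are degenerate when the two midpoints coincide within
  1e−9 mm.
- Landmark CSVs store coordinates with shortest-round-trip `repr`, so
  write → read is bit-exact; a JSON sidecar carries pixel spacing and
  image size.  Measurement CSVs print 6 decimals with a full-precision
  companion; report CSVs round to 2 decimals with the full-precision file
  alongside.
- Every generated dataset writes a manifest embedding the complete config,
  the seed, the split assignment and each case's ground-truth rotations;
  re-running with the same config reproduces it exactly.
- Desk problem sizes used by the test suite and the acceptance script:
  100 synthetic cases for recovery, 20 for invariance, ~1,300–2,000
  pairwise distances for the noise calibration, 60 cases for the simulated
  study, and 200/50/50 renders for the detector.
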