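# Methods

`ltq` quantifies blunt liver trauma on 3D contrast-enhanced CT.  It segments
the liver parenchyma and the regions disrupted by laceration or
intraparenchymal hematoma, and reports the **liver disruption involvement**

    LDI(%) = V(trauma) / V(liver) * 100,

the percentage of parenchymal volume disrupted — the volumetric quantity
behind CT-based trauma severity grading.  Volumes are voxel counts times the
unit voxel volume taken from scan metadata (slice spacing x row spacing x
column spacing).  The denominator is the whole segmented liver, normal and
affected tissue alike; a case with no detected trauma has LDI 0 by
convention.

## Pipeline

1. **Backbone.**  A slice-wise U-net (encoder-decoder CNN with skip
   connections) produces per-voxel foreground probabilities for each task,
   restacked into a 3D map on the input lattice.  Intensities are windowed
   to [-100, 300] HU and scaled to [0, 1]; probabilities are thresholded at
   0.5 by default.  The network is implemented in numpy with hand-derived
   gradients (im2col convolutions, average-pool downsampling,
   nearest-neighbour upsampling with skip concatenation, a 1x1 sigmoid
   head), trained with Adam on a BCE + soft-Dice loss.  The BCE foreground
   term is weighted by the inverse foreground fraction (capped at 50) so
   small lesions are not drowned out by background.  Training is
   bit-reproducible under a fixed seed, and a finite-difference check in the
   test suite guards the analytic gradients.  Every downstream stage accepts
   arbitrary masks, so the backbone is fully pluggable (see *Limitations*).

2. **Liver refinement.**  The initial liver mask is smoothed with a 3D
   Gaussian applied to the 0/1 indicator (sigma in millimetres, divided by
   the per-axis spacing so smoothing is isotropic in physical space;
   re-threshold at 0.5), small components are removed, axial in-plane holes
   are filled slice by slice, and only the largest 3D connected component
   survives.  Defaults: sigma 2 mm, minimum region 64 voxels,
   26-connectivity.  The stage order is fixed as listed; component-size ties
   break toward the component containing the lexicographically smallest
   (z, y, x) voxel.

3. **Trauma refinement.**  Candidate components are filtered by two domain
   rules and then refined geometrically:

   * *Location rule.*  Trauma lives inside the liver: a component is dropped
     when strictly more than 50% of its voxels fall outside the segmented
     liver.  Retained components are kept whole.
   * *Intensity rule.*  Trauma is hypodense: for each component, a Welch
     two-sample t-test compares liver-voxel intensities (excluding the
     component's own voxels) against the component's voxels.  The signed
     statistic t = (liver - candidate)/SE must reach a fixed threshold
     (default 5.0) or the component is dropped.  The signed, one-sided form
     matters: the liver reference distribution includes partial-volume rim
     voxels that pull its mean down, so a candidate of pure parenchyma
     texture tests *brighter* than the reference (t strongly negative); an
     absolute-value rule would wrongly retain it.  The threshold was
     calibrated on synthetic confounder phantoms: same-texture candidates
     give |t| of order 1-7 (negative), genuinely hypodense components of
     >= 100 voxels give t above +20.  Components smaller than 2 voxels
     cannot support the test and are dropped with a logged reason.
   * *Chan-Vese evolution* (below), clipped to the liver.
   * Morphological cleanup: remove components under 30 voxels, fill axial
     holes, intersect with the liver.

4. **Severity.**  LDI from the two final masks, with physical volumes in
   mm^3.  LDI is invariant to uniform spacing rescaling; trauma voxels
   outside the liver (only possible when upstream clipping is disabled) are
   counted but flagged.

## The Chan-Vese active contour

The surface S evolves to minimise

    F(s1, s2, S) = mu A(S) + nu V(S)
                   + lambda1 * sum_inside  |I - s1|^2
                   + lambda2 * sum_outside |I - s2|^2

with s1, s2 the mean intensities inside/outside S.  Discretely, A(S) counts
inside/outside voxel-face interfaces weighted by physical face area, V(S) is
the inside volume, and the integrals are voxel sums times the voxel volume.
Parameters: lambda1 = lambda2 = 1; mu = 0.1 (surface-area smoothness);
nu is the contraction bias — positive taxes enclosed volume and shrinks the
contour — chosen by grid search (below).

Numerical scheme and choices:

* **Sign convention**: inside = {phi < 0}; phi is a signed distance in voxel
  units, rebuilt exactly (Euclidean distance transform) after every sweep.
* **Domain restriction**: the outside region is `liver & ~inside`, and the
  inside region is clipped to the liver after every iteration.  Including
  non-hepatic background (~40 HU) in s2 would make every parenchyma voxel
  look inside-like and drive unbounded growth for any retained candidate;
  restricting the domain makes s2 the intact-parenchyma mean, which is the
  contrast the method actually uses.  The final mask is a subset of the
  liver by construction.
* **Sparse-field updates**: only the thin active band around the zero
  crossing is updated each sweep — the surface-adjacent voxels
  (|phi| <= 1) are the flip candidates, with the five-layer band |phi| <= 2
  maintained for bookkeeping.  A dense variant applies the identical update
  at every voxel and serves as a cross-check (tested to Dice >= 0.99, in
  practice bit-identical: voxels far from the surface cannot cross it in
  one sweep).
* **Exact discrete descent**: for each candidate voxel the energy change of
  moving it across the surface is evaluated in closed form — data and
  volume terms from its intensity, the area term from its six faces (the
  discrete curvature force) — and every strictly favourable flip is
  applied.  A voxel exactly at the energy balance stays put, so a perfectly
  fitted surface is stationary.  A PDE-style update with a CFL-bounded
  uniform time step was tried first and rejected: with phi rebuilt as an
  exact distance each sweep, adjacent layers sit at |phi| = 1 and a bounded
  step can never move the front.
* **Step-size control / monotonicity**: simultaneous flips interact through
  shared faces, so each sweep is accepted only if the recorded energy did
  not increase (within 1e-9 relative); otherwise it is retried with the
  strongest half of its flips.  The energy trace is therefore
  non-increasing by construction.
* **Intensity normalisation**: intensities are rescaled to [0, 1] over the
  domain (1st-99th percentile window) before evolution, keeping the printed
  parameter scales meaningful for HU data.
* **Convergence**: stop when fewer than 0.1% of band voxels change side, or
  after 200 iterations, or when no favourable flip exists.

**Contraction-bias calibration.**  nu is grid-searched over
(-0.1, -0.05, -0.02, 0, 0.02, 0.05, 0.1); a coarser +-0.3/0.1 grid is far
wider than the near-boundary data-term differences under the [0, 1]
normalisation and saturates at its ends.  Two criteria are provided:
`select_nu` maximises validation Dice (or minimises final energy when no
ground truth exists), ties resolving to the smallest |nu|;
`calibrate_nu_for_ldi` runs the full trauma chain on calibration cases and
minimises the mean absolute LDI error.  The volumetric criterion is the
right one when the endpoint is LDI: overlap scores are nearly blind to the
sub-voxel boundary offset that dominates volumetric bias.  On phantom
cohorts the calibrated bias (nu = 0.02) removes a systematic +10-15% volume
overshoot caused by s2 contamination from partial-volume rim voxels.

## Synthetic phantoms

The generator emulates a portal-venous-phase abdominal CT around the liver:

* **Organ**: union of 2-3 overlapping ellipsoids, indicator smoothed and
  re-thresholded, single 26-connected component, holes filled.
* **Trauma**: grown by randomised (Eden-type) accretion from a random-walk
  spine, then smoothed by taking the top-n voxels of its blurred indicator —
  irregular at organ scale but smooth at the voxel scale, as real
  lacerations are.  Voxel-rough blobs were rejected deliberately: under
  partial-volume blur their wide mixed-intensity halo makes the volumetric
  ground truth unrecoverable by any intensity-based method.  The voxel count
  hits the target LDI exactly (to rounding), and `true_ldi_pct` is the exact
  count ratio, so ground-truth volumetry is a machine-precision oracle.
* **Intensities**: background 40, parenchyma 110, trauma 60 HU, Gaussian
  blur sigma 0.8 voxels for partial-volume softening, additive Gaussian
  noise sd 10 HU.  These are portal-venous-plausible choices, configurable;
  published sources do not pin down typical trauma-to-liver contrast.
* **Confounders**: `fatty` lowers the organ mean by 30 HU (diffuse low
  attenuation, no trauma); `congestive` adds a smooth random field of sd
  12 HU inside the organ (heterogeneous enhancement); `streak` darkens a
  planar band of half-width 1.5 voxels by 30 HU across the volume (beam
  hardening).
* **Seeding**: one master seed fully determines a sample via independent
  child streams (organ / trauma / confounder / noise), so the confounder
  choice never perturbs the organ geometry; cohorts use seed + index per
  sample, cycling through LDI levels and dealing confounders by largest
  remainder.

What phantoms do **not** model: hepatic segments and vasculature,
multi-phase contrast, neighbouring organs of liver-like attenuation, true
scanner noise texture and reconstruction kernels.  Passing phantom tests
therefore demonstrates the correctness and calibration of the machinery,
not clinical-grade performance on patient data.

## Evaluation machinery

* Metrics: Dice, recall, precision, RVD = (|S|-|GT|)/|GT|, and
  VOE = 1 - |S n GT|/|S u GT|.  (The overlap-error formula is implemented
  with the union denominator per its standard definition.)  Empty ground
  truth flags all overlap metrics as undefined; an empty segmentation
  against non-empty ground truth reports precision 0 with a flag.
* Cross-validation: patient-wise folds balanced on reference LDI — cases
  sorted by severity and dealt round-robin with a seeded rotation; the same
  folds serve the liver and trauma tasks.
* Agreement: OLS of computed on reference LDI (slope, intercept, r, r^2)
  plus Bland-Altman bias and 1.96-SD limits of agreement, with cases outside
  the limits listed as outliers.
* Severity strata for reporting: [0, 2), [2, 5), [5, inf) percent LDI —
  right-open, so a case at exactly 2% joins the upper stratum.

## Problem sizes and defaults

Tests and the acceptance script run on 32 x 48 x 48 phantoms at
(3.0, 2.0, 2.0) mm spacing (about 50k voxels, ~20-28k of them liver), with
backbone configs of depth 2, 8 base channels, 48 x 48 input and about six
epochs — sizes chosen so the full suite and script each complete in a few
minutes on one CPU while leaving every behaviour measurable.  The default
`PhantomSpec` is 48 x 64 x 64 at (2.5, 1.5, 1.5) mm.  The default
`BackboneConfig` (depth 4, 16 base channels, 64 x 64 input) is the
full-size architecture; all of it is overridable.

## Limitations

* **Trauma backbone at miniature scale.**  With of order 10^2 CPU
  optimisation steps the trauma network does not localise lesions (training
  Dice plateaus near 0.2); a per-voxel classifier on intensity plus local
  context does no better, because trauma shares its intensity range with
  the extra-hepatic background and the discrimination must be learned as
  shape context.  The liver task, by contrast, reaches Dice ~0.95 held-out
  in the same budget.  This is why every downstream stage accepts injected
  masks: refinement, exclusion and severity are tested against oracle and
  perturbed-oracle candidates, independent of backbone quality.  At full
  scale (GPU, real cohorts) the backbone slot is designed to be replaced by
  a stronger model without touching the rest of the pipeline.
* The t-test threshold and Chan-Vese contraction bias are calibrated on
  synthetic phantoms; new acquisition protocols warrant recalibration.
* Subcapsular hematoma and active bleeding are out of scope; the pipeline
  quantifies parenchymal disruption only.
* DICOM support covers plain single-frame CT series (explicit VR little
  endian); compressed transfer syntaxes and multi-frame objects are not
  handled.
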