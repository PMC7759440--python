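# Methods

`mrideface` implements a two-stage anonymization pipeline for 3D cranial MR
volumes: a trainable facial-feature detector followed by feature-specific
distortion operators, plus DICOM header de-identification.  This note
records the models, the tunable parameters, and the numerical choices in
enough detail to audit or re-derive every result the tests and the
acceptance script compute.

## Coordinate convention

Every volume is reoriented on load to the closest-to-RAS axis order:
axis 0 runs left → right (lateral), axis 1 posterior → anterior, axis 2
inferior → superior.  Voxel indices are 0-based and boxes are half-open
intervals `[lo, hi)` per axis, so "doubling a box" is unambiguous integer
arithmetic.  The original affine is kept on the `Volume` so outputs can be
written back on the grid they came from.

## Synthetic head phantom

The phantom stands in for clinical T1 head scans so that every stage is
testable without patient data.  It is a geometric model, not an MR
simulation: an ellipsoidal head (default semi-axes 20 × 22 × 24 mm) of
tissue intensity 100 with two spherical eyes (radius 5 mm) on the
anterior-superior surface, a protruding nose ellipsoid on the anterior
midline (extent 6 mm), and two lateral auricle ellipsoids (extent 6 mm).
Ground-truth labels follow the labelling protocol the detector is meant to
learn: eye and nose labels are spheres about the feature centre (the nose
sphere restricted to tissue), ear labels are the auricle only — the part of
the ear outside the head ellipsoid — because the auricle abuts the brain
and a generous ear label would cost brain voxels during distortion.

Air is half-normal noise (the magnitude of a zero-mean Gaussian), the
simplest model of magnitude-MR background; its scale is calibrated so the
*sample standard deviation* of the air equals `air_noise_sigma` (default
5, i.e. 1/20 of tissue).  Tissue carries mild truncated-Gaussian texture
(σ = `air_noise_sigma`, clipped at ±3σ).  The texture serves two purposes:
it is realistic, and it guarantees natural tissue never forms
exactly-constant intensity runs, which the defacer's surface-search guard
relies on (below).  The default grid is 64³ voxels at 1 mm; `spec.small()`
renders the same head in millimetres on 32³ at 2 mm for fast training runs.
Cohorts jitter all radii, extents, and the tissue intensity by independent
uniform factors in `[1−j, 1+j]` (default j = 0.08).

What the phantom does *not* model: bias fields, Rician noise correlation,
partial voluming, anatomy beyond the five features.  Passing tests on
phantoms therefore demonstrate the correctness of the pipeline's logic and
the learnability of the task geometry, not clinical-grade detection
accuracy.

## Augmentation

Seven transforms are sampled independently per draw, with default ranges:
additive Gaussian noise (σ uniform in 0–0.02 of the volume's 99th-percentile
intensity), rotation −15° … +15° about each axis, axis flips with
probability 0.5 each, random axis transposition, per-axis shift of 0–0.10
of the axis extent, per-axis shear coefficient 0–0.20, and isotropic
resize 0.90–1.10.  The unitless shift range is read as a fraction of the
axis extent so the transform is resolution-independent.

Composition order is transpose → flips → one combined affine resampling
(rotation ∘ shear ∘ scale, plus translation, about the volume centre) →
noise.  A single resampling minimizes interpolation blur; noise is added
last so it is not smoothed.  Intensities are interpolated linearly, labels
by nearest neighbour (any other choice invents label codes); out-of-field
voxels are filled with 0, matching air.  Each `AugmentDraw` records the
sampled permutation, flips, matrix, and shift, and can map arbitrary input
voxel coordinates forward — the property tests use this to verify that
label-component centroids track the sampled transform within 1.5 voxels
(interpolation tolerance).

An epoch streams every original plus `k` fresh augments of each: 3 per
training image and 1 per validation image by default, which is how a
144-image training set becomes 576 images per epoch and 48 validation
images become 96.

## Detector

The detector is an attention-gated 3D U-net over 4 classes {background,
eye, nose, ear}.  Encoder level *i* applies two 3×3×3 convolutions with
ReLU at width `base · 2^i`, then 2× average pooling; the decoder mirrors
this with nearest-neighbour upsampling and a 1×1×1 projection.  Skip
connections pass through additive attention gates: skip features `x` and
upsampled decoder features `u` are projected to `base·2^i / 2` channels,
summed, ReLU-ed, and squashed to a per-voxel sigmoid attention map that
rescales `x` before concatenation.  A final 1×1×1 convolution and softmax
yield per-voxel class probabilities.  Defaults: depth 4, base 16 channels;
the desk-scale variant (`DetectorConfig.small()`) is depth 3, base 8,
32-voxel patches.  Inputs are normalized per volume to [0, 1] by robust
1st–99th percentile rescaling, which absorbs scanner-dependent intensity
scales.

The network, its backward pass, and Adam (lr 10⁻³, β = 0.9/0.999,
batch 2 via gradient accumulation) are implemented directly in NumPy
(`mrideface.nn`): convolutions evaluate as 27 shifted BLAS matrix
products, and every layer has a hand-written exact gradient (verified
against finite differences in the test suite).  At the package's target
scales — tens of thousands of parameters, 32³–64³ patches — this trains in
minutes on one CPU core.  Nearest-neighbour upsampling was chosen over
trilinear for its exact, sparse backward pass; at these scales the
difference is not measurable.

Training minimizes `(1 − soft Dice) + 0.1 × CCE`.  Soft Dice averages the
per-class smoothed ratio `(2Σpy + ε)/(Σp + Σy + ε)` with ε = 1, which is
differentiable everywhere and equals 1 exactly at a one-hot match, so the
loss is 0 only at a perfect prediction.  CCE is averaged over voxels so
the 0.1 weight is independent of patch size.  The validation metric is
hard Dice per feature class (background excluded, since its dominance
would mask feature errors), unweighted-averaged over classes present in
prediction or truth.  Early stopping: the best mean validation Dice is
checkpointed, and training stops once `patience` (default 5) epochs pass
without a new best — a run whose metric peaks at epoch 23 stops at
epoch 28.  Epochs are 1-based throughout.

Instance separation takes the argmax label map, extracts connected
components per class, discards components under 10 voxels (speckle), keeps
the two largest eye and ear components and the largest nose component, and
assigns left/right by centroid position along the lateral axis.  Absent
features are flagged, not fatal.

### Parameter-recovery experiment

The desk-scale evidence that the detector learns: 12 jittered phantoms at
32³ (2 mm), 4 validation and 4 held-out phantoms, depth-3/base-8 network,
full augmentation protocol, ≤ 15 epochs.  Held-out mean Dice over
{eye, nose, ear} reaches ≈ 0.93, and the acceptance suite requires ≥ 0.70
in at least 2 of 3 seeds.  Validation Dice during training is noticeably
lower than held-out Dice because validation images are themselves
augmented (transposed/flipped), per protocol.

## Defacing operators

All region masks, the air-noise range, and the face surface are resolved
on the *input* volume, so the operators are order-independent in their
inputs.

**Air-noise range.**  Air is sampled from the 8-voxel margin of the six
outer faces, keeping voxels below 25 % of the volume's 99th-percentile
intensity — a robust, scale-invariant cut that rejects tissue (e.g. an
auricle) touching the margin.  The range is `[0, 98th percentile]` of that
sample; for half-normal background with std σ this lands near 3.9 σ.  A
volume with no air voxels falls back to `[0, 1 % of max]` with a warning.

**Nose.**  The bounding box of the detected region is expanded to twice
its side length about its centre along each axis (new half-extent = old
full extent), clipped to the volume, and zeroed.  This is deliberately
aggressive: the nose is the most protuberant feature and its shape must
not be inferable.

**Eyes.**  A periocular box is built per eye: the eye's bounding box
expanded ×2 laterally and vertically and extended to the anterior volume
face.  Within the box, for every (lateral, vertical) column the face
surface is the first voxel exceeding `3 × air.hi` scanning from the
anterior face inward, and the ±2-voxel segment about it along the anterior
axis is set to one constant value — the median intensity of all detected
surface voxels.  The ±2 range is applied per column along the scan axis
rather than as a 3D (Chebyshev) dilation of the surface set: on a curved
surface the dilated variant paints air two voxels anterior of the surface,
which would itself become the threshold crossing on a repeated run, making
the shell creep anteriorly by two voxels per application.

Two guards make re-defacing a fixed point.  (1) *Plateau recentring*: an
exactly-constant supra-threshold run of 3–5 voxels at the crossing is
recentred to the run centre — a previously flattened shell is exactly
constant over its 5-voxel depth, whereas textured tissue never is.
(2) *Zero-cavity skip*: a column whose crossing sits behind ≥ 3 exactly-zero
voxels with nonzero air above them is skipped — that pattern is the back
wall of an already-removed nose box, never natural anatomy, where air
carries noise.

**Ears.**  Every detected auricle voxel is replaced by an independent
uniform draw from the estimated air range (seeded, hence reproducible).
Uniform is the maximum-entropy choice on an interval; the result is
indistinguishable from background in a rendering.  A degenerate range
(lo = hi) sets the constant.

**Composition.**  `deface()` applies nose → eyes → ears with voxel claims
resolved by that precedence, so the three modification zones are disjoint,
the nose box stays exactly zero even where a periocular column would cross
it, and the report's per-feature counts sum to the total.  Columns whose
eye segment would intersect the nose zone are skipped entirely (they are
inside the removed box anyway).  Consequently applying `deface` twice with
the same regions changes only ear voxels (which are legitimately re-drawn);
the test suite asserts exactly zero other changes on noisy phantoms.  On a
noise-free volume (exactly constant tissue, exactly zero air) the plateau
guard cannot distinguish shell from tissue and the fixed-point property is
not guaranteed — noise-free inputs do not occur in practice.

## DICOM de-identification

The default profile lists 20 HIPAA-safe-harbor-aligned attributes (patient
name/ID/birth date, other patient IDs/names/birth name, address, phone,
ethnic group, patient comments, institution name/address,
referring/performing/operator names, accession number, study/series dates,
study time, device serial number) with actions `remove` or `blank`; it is
serializable as a plain-text file (`group,element,action` per line) so
sites can substitute their own list.  A third action, `replace`, is
available for UID attributes: the UID is regenerated deterministically
(MD5 of the original under a fixed root), preserving series linkage, and
values already under that root are left alone — so de-identification is
idempotent.  Pixel data is never touched; every profile attribute produces
an audit record (`removed`/`blanked`/`replaced`/`absent`).  De-identified
files are always written to a new directory, never in place.

## Problem sizes

Tests and the acceptance suite run entirely on phantoms: 64³ at 1 mm for
geometry/operator checks (20 seeds for the operator contracts), 32³ at
2 mm for training (12/4/4 phantoms, ≤ 15 epochs, up to 3 seeds), 16³ at
4 mm for CLI and micro-training smoke tests.  These sizes were chosen so
the full suite runs in minutes on a single core while still exercising
every contract at realistic feature-to-voxel ratios.

## Known limitations

* The phantom's simplicity means detector scores on it say nothing
  quantitative about clinical data; only the pipeline logic and training
  machinery are validated.
* Mouth and wrinkle anonymization are out of scope, as are multi-frame
  (enhanced) DICOM, DICOM-SEG output, and rendering-based verification.
* The face-surface search scans along the anterior axis only; a volume
  whose anterior axis cannot be recovered from its affine (corrupt or
  missing orientation metadata) would need manual reorientation first.
* Left/right assignment assumes the canonical orientation; it is a
  convention for reporting, and mislabeling left versus right would not
  change which voxels are anonymized.
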