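# Methods

## The problem

Voxel-level cancer labels for prostate MRI can be derived from radiologist
outlines, from pathologist outlines on registered whole-mount histopathology,
or from a histopathology deep-learning model that assigns per-voxel Gleason
patterns.  The package's question is comparative: *how do these labeling
strategies differ, and how do those differences propagate into the
segmentation models trained with them?*  All analyses run on synthetic
co-registered phantoms, so every component — annotator imperfection, label
derivation, training, evaluation — is controlled and seeded.

## Label model

Each label volume codes voxels as 0 outside / 1 normal / 2 indolent (Gleason
pattern 3) / 3 aggressive (Gleason pattern 4+; where patterns 3 and 4
overlap, the voxel is aggressive).  Lesion formation, shared by all
strategies:

1. **Morphological closing** of the binary annotation with a 3D structuring
   element of three stacked in-plane disks of radii 0.5, 1.5, 0.5 mm (one
   slice each).  Millimetre radii convert to pixels by round-half-up with a
   one-pixel minimum — (2, 5, 2) pixels at 0.29 mm.  The element's Z-extent
   is defined in slices, not millimetres, so it spans three adjacent slices
   at any slice spacing; closing is computed with explicit padding so
   objects at the volume border are not clipped.
2. **3D connected components** (26-connectivity by default; 6 available).
3. **Volume filter**: `LV = PSx·PSy·Dz·NL` with `NL` counted on the *closed*
   mask; lesions with `LV < 250 mm³` are discarded (half the 500 mm³
   PI-RADS v2 clinical-significance threshold); exactly 250 mm³ is kept.
   Discarded lesions are retained separately for reporting.
4. **Classification** by the 1 % rule: ≥1 % aggressive voxels → aggressive;
   else ≥1 % indolent voxels → indolent; else benign (benign outlines revert
   to normal tissue).  Biopsy-style confirmations use the grade-group rule
   instead: GG ≥ 2 aggressive, GG 1 indolent, benign → normal.

Voxels added by closing carry no grade.  For lesion-level labels they simply
inherit the lesion class; for `LPixelDPath` they take the majority cancer
code within the structuring-element neighbourhood (ties aggressive, matching
the overlap convention), falling back to the lesion-wide majority.

Whether `NL` should be counted before or after closing is not determined by
the lesion-formation description alone; post-closing is used because the
filter is defined on "the 3D lesion after morphological closing and
connected component analysis".

## Synthetic cohorts

Each case is a pure function of (spec, case seed); cohorts use per-case
seeds derived by counter from a master seed so extending a cohort never
reshuffles earlier cases.

* **Geometry.**  The prostate is a jittered ellipsoid (≈44 × 34 mm in-plane,
  spanning ~80 % of slices).  Lesions are random-axis ellipsoids, in-plane
  semi-axes 5–8 mm and through-plane 3.5–7 mm, placed by drawing radii first
  and then sampling a centre uniformly from the admissible region (computed
  by convolving the gland complement and the separation zone with the lesion
  footprint).  Lesions must stay ≥5 mm apart in-plane and ≥3 slices apart
  along Z — beyond the closing kernel's reach, so planted lesions can never
  be merged by label derivation; this makes planted-class recovery an exact
  (100 %) expectation, and the tests assert it as such.  If no fully
  contained centre exists, lesions clipped by the gland boundary are
  accepted late in the search provided ≥60 % of the ellipsoid survives and
  the clipped volume stays ≥300 mm³, which keeps every planted lesion above
  the 250 mm³ filter.
* **Grades.**  25 % of lesions are pure Gleason-pattern-3 (grade group 1);
  the rest carry a nested GP4+ core occupying a drawn fraction (0.3–0.8) of
  the lesion volume, giving the mixed lesions that distinguish pixel-level
  from lesion-level labels.
* **Intensities.**  One background level per tissue per modality, a relative
  signal drop (default 0.35) inside lesions, in-plane Gaussian smoothing
  (σ = 1 px) and additive Gaussian noise (σ = 0.05).  GP4+ voxels get 1.4×
  the drop on ADC, emulating the stronger diffusion restriction of
  higher-grade cancer — without it the aggressive-vs-indolent task would
  carry no image signal at all.
* **Conspicuity.**  With probability `rad_miss_prob` (default 0.2) a lesion
  is "hardly visible": rendered at 0.12× contrast (≈3× the smoothed noise
  floor) and never outlined by the radiologist.  Tying the miss to low
  contrast, rather than drawing it independently, reproduces the actual
  mechanism of radiologist misses (MRI-invisible tumours) and is what makes
  label-quality effects on trained models observable; the aggregate miss
  rate is unchanged.
* **Radiologist outlines** of the visible lesions are eroded per-slice
  towards a target volume ratio and then lose slices with probability 0.1.
  The erosion target is `rad_shrink_factor³ / (1 − skip)` so the *net*
  outline/lesion volume ratio, skipped slices included, calibrates to
  `rad_shrink_factor³ ≈ 0.68` at the default 0.88 linear factor (verified
  band 0.58–0.78 over 200 lesions).
* **Pathologist outlines** carry the full lesion extent on annotated slices,
  drop each lesion-slice independently with probability 0.2, and carry no
  grade information.

What the phantoms deliberately do **not** model: MRI physics (no b-values,
no ADC computation), registration error between modalities or between MRI
and histology (volumes are born co-registered), anatomical zonal structure,
and non-ellipsoidal lesion shapes.  Passing tests therefore demonstrate the
correctness and direction-of-effect of the *pipeline*, not clinical
performance on real data.

## Models

The segmentation networks are compact numpy encoder–decoders (3×3
convolutions, ReLU, 2×2 average-pooling, nearest-neighbour upsampling,
≤2 M parameters) with manual backpropagation and Adam.  Four variants keep
the field's input/output conventions: `spcnet_like` (2.5D: three consecutive
slices of T2w and ADC, six input channels), `unet_like` (2.5D with skip
connections), `branched_unet_like` (two decoder heads — cancer vs normal and
aggressive vs indolent — merged as `p = (q_n, q_c·r_i, q_c·r_a)`), and
`deeplab_like_2d` (single-slice, two channels, dilated bottleneck).  The
`_like` suffix is deliberate: these are small stand-ins that preserve the
training contracts, not reimplementations of the published architectures.

Training minimizes cross-entropy over prostate voxels only (outside voxels
contribute neither loss nor gradient — asserted by a zeroed-gradient test),
weighted by inverse class frequency over the training set, capped at 100 and
normalized to mean 1.  Historical hyperparameters are kept as defaults
(batch 22, 30 epochs, learning rates 1e-4 / 1e-5 / 1e-3 per architecture);
the desk preset used by the study pipeline and tests trains 12 cases for
3 epochs at batch 4 and lr 1e-3 on a 96 × 96 / 0.6 mm grid — sizes chosen so
a full study runs in about a minute on one CPU while the label-quality
ordering remains measurable.  Prediction is slice-wise softmax assembled
into a 3D probability volume; hard labels are the voxelwise argmax inside
the prostate with no morphological post-processing.

## Evaluation

Per patient and per task (cancer = codes {2,3}, aggressive = {3}, indolent =
{2}):

* **Units.**  Positives are the kept ground-truth lesions of the task class;
  negatives are sextants — left/right of the mask's x-centroid × three
  contiguous Z-thirds (base/mid/apex, remainder slices to the base) — that
  contain no task-positive voxel.  Sextants overlapping any positive lesion
  yield no unit, so the same territory is never counted both ways.
* **Scores.**  The maximum task probability over the unit's voxels (95th
  percentile and mean are available; max is the default convention).  ROC-AUC
  is the rank-based Mann–Whitney statistic with ties counted ½, undefined
  when either unit class is empty.
* **Operating point.**  Sensitivity/specificity default to the hard argmax
  segmentation (a lesion is detected if any voxel is argmax-assigned the
  task class); fixed thresholds are available.  Dice compares the hard task
  mask with the label task mask.
* **Aggregation.**  Cohort cells report mean ± population std (ddof = 0)
  over patients; undefined patient values are excluded and the per-cell `n`
  is reported, never silently zeroed.

Cross-label matrices evaluate each trained model against every label type
(4 × 4 on the surgical-style test cohort; against `LRad` only on the
biopsy-style cohort, whose lesions are re-classed by a simulated targeted
biopsy — grade map sampled at the lesion, small configurable error rate,
mapped through the grade-group rule).  Label concordance uses the same
machinery with one label type acting as a degenerate (0/1-probability)
predictor.

## Numerical conventions and edge cases

* Volumes are indexed (z, y, x), 0-based; "left" is the low-x half by
  default (a laterality flag flips it).
* Sextant partitioning requires ≥3 prostate-bearing slices; cropping refuses
  to truncate a gland larger than the target field of view; z-score
  normalization rejects constant volumes.
* A closing with a round-disk kernel cannot bridge a gap between *isolated
  voxels* (the disk corner above the gap is never covered during erosion);
  gap-bridging holds for annotation blobs larger than the kernel footprint,
  and the tests exercise exactly that case.
* Intensity standardization recipes vary between sites; both implemented
  methods (masked z-score, decile-landmark mapping) are approximations and
  selectable in configuration.
* Determinism: every stochastic step derives from `numpy.random.SeedSequence`
  children of the master seed; the full desk study reruns byte-identically.

## Known limitations

Desk-scale training runs are short and individual runs are noisy; the study
pipeline reports single-seed matrices, while ordering claims in the tests
use medians over three seeds.  Lesion-level AUC on small cohorts is coarse
(few units per patient).  The max-score convention saturates for extremely
overconfident models — every unit containing one confident false-positive
voxel ties at 1.0 — which is a property of the convention itself; the 95th
percentile alternative is provided.  The biopsy-confirmation error process
is a free parameter, not a calibrated reproduction.
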