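# prostatelab

Tools for studying **how the choice of ground-truth labels affects machine
learning models that detect prostate cancer on MRI**.

Training a "digital radiologist" — a model that marks each prostate voxel on
T2-weighted (T2w) and apparent-diffusion-coefficient (ADC) images as normal
tissue, indolent cancer (Gleason pattern 3) or aggressive cancer (Gleason
pattern 4+) — requires voxel-level ground truth, and that ground truth can
come from very different sources: radiologist outlines confirmed by
pathology, pathologist outlines on whole-mount histopathology, or per-voxel
Gleason-pattern maps produced by a histopathology deep-learning model (a
"digital pathologist").  Human labels are imperfect in characteristic ways:
radiologists miss MRI-invisible tumours and underestimate lesion extent;
pathologists skip slices.  This package implements the full comparison
pipeline for the four label strategies

| label type | source | granularity |
|---|---|---|
| `LRad` | radiologist outlines, pathology-confirmed | lesion |
| `LPath` | pathologist cancer outlines, graded by the grade map | lesion |
| `LLesionDPath` | digital-pathologist grade map | lesion |
| `LPixelDPath` | digital-pathologist grade map | voxel |

and exercises it end to end on synthetic, born-co-registered phantom
cohorts, since the institutional imaging/histopathology cohorts such
analyses are run on cannot be redistributed.

## What is implemented

* **Synthetic cohorts** (`prostatelab.phantom`) — seeded phantoms with T2w +
  ADC volumes (default 224 × 224 at 0.29 mm, 3 mm slices), a prostate mask, a
  per-voxel grade map, and simulated radiologist/pathologist outlines with
  calibrated imperfections (≈20 % missed lesions, outline volume ≈68 % of
  lesion volume, skipped slices).
* **Label derivation** (`prostatelab.labels`) — lesion formation by
  morphological closing (stacked disks of 0.5/1.5/0.5 mm) + 3D connected
  components; lesion volume `LV = PSx·PSy·Dz·NL`; discarding of lesions
  below 250 mm³; the 1 %-of-volume aggressiveness rule; the grade-group
  mapping for biopsy-confirmed lesions (GG ≥ 2 aggressive, GG 1 indolent).
* **Preprocessing** (`prostatelab.preprocess`) — cropping/resampling around
  the gland, masked z-score and decile-landmark intensity normalization,
  2.5D slice stacking.
* **Models** (`prostatelab.models`) — small trainable 3-class encoder–decoder
  segmentation networks (`spcnet_like`, `unet_like`, `branched_unet_like`,
  `deeplab_like_2d`) written in pure numpy with Adam and a class-balanced
  cross-entropy restricted to prostate voxels.
* **Evaluation** (`prostatelab.evaluation`) — sextant-based lesion-level
  metrics: per-patient ROC-AUC (positives = ground-truth lesions, negatives
  = lesion-free sextants), sensitivity, specificity and Dice, aggregated as
  cohort mean ± std; 4 × 4 train-label × eval-label matrices.
* **Study pipeline + CLI** (`prostatelab.pipeline`, `prostatelab` command) —
  label-concordance analysis and the full simulate → label → train →
  cross-evaluate study.

## Worked example

```python
import prostatelab as pm
from prostatelab import pipeline as pl

cohort = pm.generate_cohort(pm.PhantomSpec(), 10, seed=42)
res = pl.run_label_concordance(cohort, label_types=("LRad", "LPath", "LLesionDPath"),
                               tasks=("cancer",))
dice = res["matrices"]["cancer"]["dice"]
print(dice.round(3))
```

prints the pairwise cancer Dice matrix (rows act as prediction, columns as
ground truth):

```
               LRad  LPath  LLesionDPath
LRad          1.000  0.601         0.648
LPath         0.601  1.000         0.816
LLesionDPath  0.648  0.816         1.000
```

Radiologist outlines overlap pathologist outlines far less (Dice 0.60) than
the digital-pathologist labels do (Dice 0.82): the annotator imperfections —
missed lesions, shrunken outlines, skipped slices — show up directly in the
concordance, which is the effect the downstream training comparison probes.

The same study from the shell:

```bash
prostatelab simulate --n 40 --seed 13 --out cohort/
prostatelab derive-labels --cohort cohort/ --out lesions.csv
prostatelab concordance --cohort cohort/ --out concordance/
prostatelab run-study --seed 13 --out study_out/   # desk-scale full study
```

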