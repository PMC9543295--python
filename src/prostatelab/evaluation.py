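"""Sextant-based lesion-level evaluation of 3-class prostate segmentations.

The evaluation mirrors how systematic prostate biopsies are read: true
positives and false negatives are counted per ground-truth lesion, while true
negatives and false positives are counted per *sextant* — the prostate split
into left/right halves, each divided into three roughly equal Z regions
(base, mid, apex).  Each unit gets a score (by default the maximum predicted
task probability inside it) and the units feed a rank-based ROC-AUC,
sensitivity/specificity at an operating point, and a voxel-wise Dice
coefficient.  All metrics are per patient; cohort cells report mean +/- std
(population std, ddof=0) over patients with a defined value.

Tasks: ``cancer`` (indolent + aggressive), ``aggressive``, ``indolent``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import labels as lab
from .labels import LabelVolume

TASKS = ("cancer", "aggressive", "indolent")

#: class-probability channel layout of prediction volumes: (normal, indolent,
#: aggressive), each of shape (z, y, x).
N_CLASSES = 3

_TASK_CODES = {"cancer": (lab.CODE_INDOLENT, lab.CODE_AGGRESSIVE),
               "aggressive": (lab.CODE_AGGRESSIVE,),
               "indolent": (lab.CODE_INDOLENT,)}
_TASK_CLASSES = {"cancer": ("indolent", "aggressive"),
                 "aggressive": ("aggressive",),
                 "indolent": ("indolent",)}
_TASK_CHANNELS = {"cancer": (1, 2), "aggressive": (2,), "indolent": (1,)}


@dataclass
class SextantPartition:
    """Assignment of every prostate voxel to one of six regions (1..6)."""

    sextant_ids: np.ndarray          # (z, y, x), 0 outside the prostate
    slice_groups: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]
    midline_x: float

    def region_mask(self, sextant: int) -> np.ndarray:
        return self.sextant_ids == sextant


@dataclass
class DetectionRecord:
    unit_kind: str      # "lesion" | "sextant"
    truth: str          # "positive" | "negative"
    score: float
    detected: bool      # under the hard-argmax operating point


@dataclass
class PatientEval:
    task: str
    roc_auc: float | None
    dice: float | None
    sensitivity: float | None
    specificity: float | None
    n_pos_units: int
    n_neg_units: int


# ---------------------------------------------------------------------------
# sextants
# ---------------------------------------------------------------------------

def partition_sextants(prostate_mask: np.ndarray) -> SextantPartition:
    """Split the prostate into left/right x base/mid/apex sextants.

    Left/right are separated at the x-centroid of the whole mask; the slices
    containing prostate are split into three contiguous groups as equal as
    possible, any remainder going to the base-most groups first.  Sextant ids:
    ``side * 3 + third + 1`` with side 0 for x < centroid, thirds ordered
    base, mid, apex (base = lowest slice indices by convention).
    """
    mask = np.asarray(prostate_mask).astype(bool)
    if not mask.any():
        raise ValueError("prostate mask is empty")
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    if len(zs) < 3:
        raise ValueError("prostate spans fewer than 3 slices; cannot form thirds")

    n = len(zs)
    base_size = n // 3
    rem = n % 3
    sizes = [base_size + (1 if i < rem else 0) for i in range(3)]
    groups, start = [], 0
    for s in sizes:
        groups.append(tuple(int(z) for z in zs[start:start + s]))
        start += s

    _, _, xx = np.nonzero(mask)
    mid_x = xx.mean()
    third_of_slice = np.full(mask.shape[0], -1, dtype=np.int8)
    for t, grp in enumerate(groups):
        for z in grp:
            third_of_slice[z] = t
    x_idx = np.arange(mask.shape[2])
    side = (x_idx >= mid_x).astype(np.int8)  # 0 = low-x side, 1 = high-x side
    ids = np.zeros(mask.shape, dtype=np.int8)
    thirds = third_of_slice[:, None, None]
    ids = np.where(mask & (thirds >= 0),
                   side[None, None, :] * 3 + thirds + 1, 0).astype(np.int8)
    return SextantPartition(sextant_ids=ids,
                            slice_groups=tuple(groups), midline_x=float(mid_x))


# ---------------------------------------------------------------------------
# task masks and unit scoring
# ---------------------------------------------------------------------------

def task_positive_mask(label_volume: LabelVolume | np.ndarray, task: str) -> np.ndarray:
    """Binary ground-truth mask for a task (cancer = codes {2,3}, etc.)."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    codes = label_volume.codes if isinstance(label_volume, LabelVolume) else label_volume
    out = np.zeros(codes.shape, dtype=bool)
    for c in _TASK_CODES[task]:
        out |= codes == c
    return out


def _task_probability(pred_prob: np.ndarray, task: str) -> np.ndarray:
    return pred_prob[list(_TASK_CHANNELS[task])].sum(axis=0)


def _hard_labels(pred_prob: np.ndarray, prostate_mask: np.ndarray) -> np.ndarray:
    hard = np.argmax(pred_prob, axis=0) + 1  # classes -> codes 1..3
    return np.where(prostate_mask, hard, 0).astype(np.int16)


def score_units(
    pred_prob: np.ndarray,
    label_volume: LabelVolume,
    partition: SextantPartition,
    task: str,
    prostate_mask: np.ndarray | None = None,
    score_statistic: str = "max",
) -> list[DetectionRecord]:
    """Score detection units: ground-truth lesions (+) and clean sextants (-).

    Each ground-truth lesion of the task class yields one positive record
    whose score is the chosen statistic (default max) of the task probability
    over its voxels.  Each sextant containing no task-positive ground-truth
    voxel yields one negative record scored over the sextant; sextants
    overlapping any task-positive lesion yield no record, so the same
    territory is never counted both ways.  The ``detected`` flag uses the
    hard-argmax segmentation (a positive lesion is detected when any of its
    voxels is argmax-assigned to the task class; a sextant is clean when none
    is).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if pred_prob.ndim != 4 or pred_prob.shape[0] != N_CLASSES:
        raise ValueError("prediction must have shape (3, z, y, x)")
    if pred_prob.shape[1:] != label_volume.codes.shape:
        raise ValueError("prediction and label grids differ")
    mask = (np.asarray(prostate_mask).astype(bool) if prostate_mask is not None
            else label_volume.codes > 0)
    sums = pred_prob.sum(axis=0)[mask]
    if sums.size and np.abs(sums - 1.0).max() > 1e-4:
        raise ValueError("class probabilities do not sum to 1 inside the prostate")

    stat = {"max": np.max, "mean": np.mean,
            "p95": lambda v: np.percentile(v, 95)}.get(score_statistic)
    if stat is None:
        raise ValueError(f"unknown score statistic {score_statistic!r}")

    task_prob = _task_probability(pred_prob, task)
    hard = _hard_labels(pred_prob, mask)
    hard_pos = task_positive_mask(hard, task)
    truth_pos = task_positive_mask(label_volume, task)

    records: list[DetectionRecord] = []
    for les in label_volume.lesion_set.kept:
        if les.lesion_class not in _TASK_CLASSES[task]:
            continue
        vox = tuple(les.voxels.T)
        records.append(DetectionRecord(
            unit_kind="lesion", truth="positive",
            score=float(stat(task_prob[vox])),
            detected=bool(hard_pos[vox].any()),
        ))
    for sextant in range(1, 7):
        region = partition.region_mask(sextant)
        if not region.any():
            continue
        if (region & truth_pos).any():
            continue  # overlaps ground truth: not a negative unit
        records.append(DetectionRecord(
            unit_kind="sextant", truth="negative",
            score=float(stat(task_prob[region])),
            detected=bool(hard_pos[region].any()),
        ))
    return records


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def lesion_roc_auc(records: list[DetectionRecord]) -> float | None:
    """Rank-based (Mann-Whitney) AUC of positive vs negative unit scores.

    Ties contribute 1/2.  Undefined (``None``) when either class is empty;
    undefined values are excluded from cohort means.
    """
    pos = np.array([r.score for r in records if r.truth == "positive"])
    neg = np.array([r.score for r in records if r.truth == "negative"])
    if len(pos) == 0 or len(neg) == 0:
        return None
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def sens_spec(records: list[DetectionRecord],
              operating_threshold: float | None = None
              ) -> tuple[float | None, float | None]:
    """Sensitivity and specificity of unit detection.

    With a numeric threshold a positive unit is detected when its score is at
    least the threshold (and a negative unit is clean when its score is
    below it).  With ``None`` the hard-argmax ``detected`` flags are used.
    Either value is ``None`` when its denominator is zero.
    """
    if operating_threshold is not None and not 0 <= operating_threshold <= 1:
        raise ValueError("operating threshold must lie in [0, 1]")
    pos = [r for r in records if r.truth == "positive"]
    neg = [r for r in records if r.truth == "negative"]

    def hit(r: DetectionRecord) -> bool:
        if operating_threshold is None:
            return r.detected
        return r.score >= operating_threshold

    sens = sum(hit(r) for r in pos) / len(pos) if pos else None
    spec = sum(not hit(r) for r in neg) / len(neg) if neg else None
    return sens, spec


def dice(pred_mask: np.ndarray, label_mask: np.ndarray) -> float | None:
    """Dice coefficient ``2|A & B| / (|A| + |B|)``; ``None`` if both empty."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(label_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = a.sum() + b.sum()
    if denom == 0:
        return None
    return float(2.0 * np.count_nonzero(a & b) / denom)


def evaluate_patient(
    pred_prob: np.ndarray,
    label_volume: LabelVolume,
    prostate_mask: np.ndarray,
    task: str,
    operating_threshold: float | None = None,
    score_statistic: str = "max",
) -> PatientEval:
    """Full per-patient lesion-level evaluation for one task.

    Composes the sextant partition, unit scoring, rank AUC, sensitivity and
    specificity at the operating point (default: the hard-argmax
    segmentation), and Dice between the hard predicted task mask and the
    ground-truth task mask.
    """
    partition = partition_sextants(prostate_mask)
    records = score_units(pred_prob, label_volume, partition, task,
                          prostate_mask=prostate_mask,
                          score_statistic=score_statistic)
    auc = lesion_roc_auc(records)
    sens, spec = sens_spec(records, operating_threshold)
    hard = _hard_labels(pred_prob, prostate_mask)
    d = dice(task_positive_mask(hard, task), task_positive_mask(label_volume, task))
    n_pos = sum(r.truth == "positive" for r in records)
    n_neg = sum(r.truth == "negative" for r in records)
    return PatientEval(task=task, roc_auc=auc, dice=d, sensitivity=sens,
                       specificity=spec, n_pos_units=n_pos, n_neg_units=n_neg)


METRICS = ("roc_auc", "dice", "sensitivity", "specificity")


def aggregate_cohort(patient_evals: list[PatientEval]) -> dict[str, dict]:
    """Cohort mean +/- std per metric, excluding undefined patient values.

    Returns ``{metric: {"mean": m, "std": s, "n": k}}`` with population std
    (ddof=0).  A metric undefined for every patient is flagged with
    ``mean=None`` and ``n=0`` rather than silently reported as zero.
    """
    out = {}
    for metric in METRICS:
        vals = [getattr(p, metric) for p in patient_evals]
        vals = [v for v in vals if v is not None]
        if not vals:
            out[metric] = {"mean": None, "std": None, "n": 0}
        else:
            arr = np.asarray(vals, dtype=float)
            out[metric] = {"mean": float(arr.mean()),
                           "std": float(arr.std(ddof=0)), "n": len(vals)}
    return out


def label_to_probability(label_volume: LabelVolume,
                         prostate_mask: np.ndarray) -> np.ndarray:
    """One-hot class-probability volume from a hard label (for concordance).

    Treating one label type as a degenerate predictor lets labels be compared
    with the same lesion-level machinery used for model predictions.
    """
    mask = np.asarray(prostate_mask).astype(bool)
    prob = np.zeros((N_CLASSES,) + label_volume.codes.shape)
    codes = np.where(mask, np.maximum(label_volume.codes, 1), 0)
    for cls in range(N_CLASSES):
        prob[cls] = (codes == cls + 1)
    prob[0] = np.where(mask, prob[0], 1.0)  # normalized outside the gland too
    return prob


def cross_label_matrix(
    evals_by_pair: dict[tuple[str, str], list[PatientEval]],
    train_labels: list[str],
    eval_labels: list[str],
) -> dict[str, pd.DataFrame]:
    """Render per-metric train-label x eval-label matrices.

    ``evals_by_pair[(train_label, eval_label)]`` holds per-patient evaluations
    of models trained with ``train_label`` scored against ``eval_label``.
    Cells for missing combinations are marked absent (NaN).  Values are
    formatted ``mean +/- std`` downstream; numeric frames carry the means.
    """
    out = {}
    for metric in METRICS:
        mean_df = pd.DataFrame(index=train_labels, columns=eval_labels, dtype=float)
        std_df = pd.DataFrame(index=train_labels, columns=eval_labels, dtype=float)
        n_df = pd.DataFrame(0, index=train_labels, columns=eval_labels, dtype=int)
        for (tr, ev), pevals in evals_by_pair.items():
            agg = aggregate_cohort(pevals)[metric]
            if agg["n"] > 0:
                mean_df.loc[tr, ev] = agg["mean"]
                std_df.loc[tr, ev] = agg["std"]
            n_df.loc[tr, ev] = agg["n"]
        out[metric] = mean_df
        out[f"{metric}_std"] = std_df
        out[f"{metric}_n"] = n_df
    return out
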