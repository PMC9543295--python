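"""Orchestration of the full labeling-strategy study on synthetic cohorts.

``run_label_concordance`` compares the four label types against each other
without any model training (one label as a degenerate predictor, the other as
truth) and reports lesion-count/volume statistics including the discarded-
lesion distributions.

``run_full_comparison`` runs the study analog end to end: simulate cohorts,
derive labels, train per-(architecture x train-label) models in
cross-validation, evaluate every model against every label type on the
held-out surgical-style cohort (4 x 4 matrices per metric and task), and
against radiologist labels only on the biopsy-style cohort.  All outputs are
CSV/JSON regenerated purely from the configuration and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import labels as lab
from . import models as mdl
from . import phantom as ph
from .preprocess import ImageVolume, normalize_intensity

logger = logging.getLogger("prostatelab")

LESION_LABEL_TYPES = list(lab.LABEL_TYPES)


@dataclass
class StudyConfig:
    spec: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    n_train: int = 12
    n_test_c1: int = 8
    n_test_c2: int = 8
    label_types: tuple[str, ...] = tuple(lab.LABEL_TYPES)
    archs: tuple[str, ...] = ("spcnet_like",)
    tasks: tuple[str, ...] = ("cancer", "aggressive")
    epochs: int = 3
    n_folds: int = 1
    batch_size: int = 4
    lr: float | None = 1e-3
    width: int = 8
    connectivity: int = 26
    score_statistic: str = "max"
    c2_confirm_error: float = 0.1
    master_seed: int = 13
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        bad = set(self.label_types) - set(lab.LABEL_TYPES)
        if bad:
            raise ValueError(f"unknown label types: {sorted(bad)}")

    def config_hash(self) -> str:
        d = to_plain(asdict(self))
        d.pop("out_dir", None)  # identical studies hash equal wherever written
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec_raw = raw.pop("spec", {})
        spec = ph.PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in spec_raw.items()})
        for key in ("label_types", "archs", "tasks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(spec=spec, **raw)


def desk_preset(master_seed: int = 13, out_dir: str = "study_out") -> StudyConfig:
    """A small configuration that runs the whole study on one CPU in minutes.

    The phantom grid is 96 x 96 at 0.6 mm pixels (the gland still spans
    ~45 mm) with 10 slices; training uses one fold, 3 epochs, batch 4 and a
    larger learning rate suited to the short schedule.  All mm-denominated
    rules (250 mm^3 filter, 0.5/1.5/0.5 mm kernel, sextants) are unchanged.
    """
    spec = ph.PhantomSpec(grid_x=96, grid_y=96, n_slices=10, pixel_size_mm=0.6,
                          slice_spacing_mm=3.0)
    return StudyConfig(spec=spec, master_seed=master_seed, out_dir=out_dir)


def to_plain(obj):
    """Recursively convert numpy/tuple values for JSON/YAML serialization."""
    if isinstance(obj, dict):
        return {k: to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# label derivation over a cohort
# ---------------------------------------------------------------------------

def derive_case_labels(case: ph.PhantomCase,
                       label_types=lab.LABEL_TYPES,
                       connectivity: int = 26) -> dict[str, lab.LabelVolume]:
    """Derive the requested label types for one phantom case."""
    source = {"LRad": case.rad_outline, "LPath": case.path_outline,
              "LLesionDPath": None, "LPixelDPath": None}
    return {lt: lab.derive_label(source[lt], case.truth_grade_map, lt,
                                 case.prostate_mask, connectivity=connectivity)
            for lt in label_types}


def derive_cohort_labels(cases: list[ph.PhantomCase],
                         label_types=lab.LABEL_TYPES,
                         connectivity: int = 26
                         ) -> dict[str, dict[str, lab.LabelVolume]]:
    """``{case_id: {label_type: LabelVolume}}`` for a cohort."""
    return {c.case_id: derive_case_labels(c, label_types, connectivity)
            for c in cases}


def cohort_lesion_table(labels_by_case: dict[str, dict[str, lab.LabelVolume]]
                        ) -> pd.DataFrame:
    frames = [f for f in (lab.lesion_table(lvs, cid)
                          for cid, lvs in sorted(labels_by_case.items())) if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def lesion_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-label-type kept/discarded lesion counts and volume statistics."""
    rows = []
    for (lt, kept), grp in table.groupby(["label_type", "kept"]):
        vols = grp["volume_mm3"]
        rows.append(dict(
            label_type=lt, kept=bool(kept), n_lesions=len(grp),
            n_aggressive=int((grp["lesion_class"] == "aggressive").sum()),
            n_indolent=int((grp["lesion_class"] == "indolent").sum()),
            volume_mean=float(vols.mean()), volume_std=float(vols.std(ddof=0)),
            volume_median=float(vols.median()),
        ))
    return pd.DataFrame(rows).sort_values(["label_type", "kept"],
                                          ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# label concordance (no training)
# ---------------------------------------------------------------------------

def run_label_concordance(
    cases: list[ph.PhantomCase],
    labels_by_case: dict[str, dict[str, lab.LabelVolume]] | None = None,
    label_types=lab.LABEL_TYPES,
    tasks: tuple[str, ...] = ("cancer", "aggressive"),
    connectivity: int = 26,
) -> dict:
    """Pairwise concordance between label types, without model training.

    For every ordered pair (A, B), label A's hard codes act as a degenerate
    predictor (probability 1/0) evaluated against label B with the standard
    lesion-level machinery, giving Dice and lesion ROC-AUC matrices per task,
    plus lesion-count/volume statistics.
    """
    if labels_by_case is None:
        labels_by_case = derive_cohort_labels(cases, label_types, connectivity)
    label_types = list(label_types)
    evals: dict[str, dict[tuple[str, str], list[ev.PatientEval]]] = {
        t: {(a, b): [] for a in label_types for b in label_types} for t in tasks}
    for case in cases:
        lvs = labels_by_case[case.case_id]
        probs = {lt: ev.label_to_probability(lvs[lt], case.prostate_mask)
                 for lt in label_types}
        for a in label_types:
            for b in label_types:
                for task in tasks:
                    evals[task][(a, b)].append(
                        ev.evaluate_patient(probs[a], lvs[b], case.prostate_mask,
                                            task))
    matrices = {task: ev.cross_label_matrix(evals[task], label_types, label_types)
                for task in tasks}
    table = cohort_lesion_table(labels_by_case)
    return {"matrices": matrices, "lesion_table": table,
            "lesion_statistics": lesion_statistics(table) if len(table) else table}


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

def _case_samples(case: ph.PhantomCase, label_volume: lab.LabelVolume,
                  input_mode: str):
    t2 = normalize_intensity(case.t2w, case.prostate_mask)
    ad = normalize_intensity(case.adc, case.prostate_mask)
    X = mdl.assemble_inputs(t2, ad, input_mode)
    return X, label_volume.codes, case.prostate_mask


def build_training_arrays(cases, labels_by_case, label_type, input_mode):
    Xs, Ys, Ms = [], [], []
    for case in cases:
        X, y, m = _case_samples(case, labels_by_case[case.case_id][label_type],
                                input_mode)
        Xs.append(X)
        Ys.append(y)
        Ms.append(m)
    return (np.concatenate(Xs), np.concatenate(Ys),
            np.concatenate([np.asarray(m) for m in Ms]))


def train_label_model(cases, labels_by_case, label_type: str,
                      config: mdl.TrainConfig) -> tuple[mdl.SegModel, mdl.TrainHistory]:
    """Train one digital radiologist on a cohort with one label type."""
    cfg = config.resolved()
    X, Y, M = build_training_arrays(cases, labels_by_case, label_type,
                                    cfg.input_mode)
    model = mdl.build_model(cfg)
    history = mdl.train(model, X, Y, M, cfg)
    return model, history


def predict_case(model: mdl.SegModel, case: ph.PhantomCase):
    t2 = normalize_intensity(case.t2w, case.prostate_mask)
    ad = normalize_intensity(case.adc, case.prostate_mask)
    return mdl.predict(model, t2, ad, case.prostate_mask)


# ---------------------------------------------------------------------------
# C2-analog biopsy confirmation
# ---------------------------------------------------------------------------

def biopsy_confirmed_labels(case: ph.PhantomCase, lrad: lab.LabelVolume,
                            error_rate: float, rng: np.random.Generator
                            ) -> lab.LabelVolume:
    """Re-class radiologist lesions through a simulated targeted biopsy.

    Each kept radiologist lesion is assigned a grade group by sampling the
    grade map around the lesion centroid (GP4+ present -> grade group 2, GP3
    only -> 1, neither -> benign); with probability ``error_rate`` the biopsy
    reads an adjacent category instead (sampling error).  The grade group is
    then mapped back to a class through the grade-group rule.
    """
    codes = np.where(case.prostate_mask, lab.CODE_NORMAL, lab.CODE_OUTSIDE).astype(np.int16)
    new_kept = []
    for les in lrad.lesion_set.kept:
        grades = case.truth_grade_map.codes[tuple(les.voxels.T)]
        if (grades == lab.CODE_AGGRESSIVE).any():
            gg: object = 2
        elif (grades == lab.CODE_INDOLENT).any():
            gg = 1
        else:
            gg = "benign"
        if rng.random() < error_rate:
            ladder = ["benign", 1, 2]
            i = ladder.index(gg)
            gg = ladder[max(0, i - 1)] if rng.random() < 0.5 else ladder[min(2, i + 1)]
        cls = lab.classify_from_grade_group(gg)
        les = replace_lesion_class(les, cls)
        if cls in ("aggressive", "indolent"):
            codes[tuple(les.voxels.T)] = (lab.CODE_AGGRESSIVE if cls == "aggressive"
                                          else lab.CODE_INDOLENT)
            new_kept.append(les)
    lesion_set = lab.LesionSet(kept=new_kept, discarded=lrad.lesion_set.discarded,
                               provenance="LRad")
    return lab.LabelVolume(codes=codes, label_type="LRad", lesion_set=lesion_set,
                           pixel_size_mm=lrad.pixel_size_mm,
                           slice_spacing_mm=lrad.slice_spacing_mm)


def replace_lesion_class(les: lab.Lesion, cls: str) -> lab.Lesion:
    out = lab.Lesion(lesion_id=les.lesion_id, voxels=les.voxels, NL=les.NL,
                     volume_mm3=les.volume_mm3, n_aggressive=les.n_aggressive,
                     n_indolent=les.n_indolent,
                     lesion_class="benign" if cls == "normal" else cls)
    return out


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def _fmt(df: pd.DataFrame) -> str:
    return df.to_csv(float_format="%.6f")


def run_full_comparison(config: StudyConfig) -> dict:
    """Simulate, derive labels, train, and emit the cross-label report.

    Returns the report dict and, when ``config.out_dir`` is set, writes CSV
    matrices, per-patient metrics, lesion tables and a JSON summary there.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.master_seed)
    logger.info("study start: hash=%s seed=%d", config.config_hash(), seed)

    spec = config.spec
    train_cases = ph.generate_cohort(spec, config.n_train, seed=seed)
    c1_cases = ph.generate_cohort(spec, config.n_test_c1, seed=seed + 10_000)
    c2_spec = replace(spec, rad_miss_prob=min(1.0, spec.rad_miss_prob * 0.75))
    c2_cases = ph.generate_cohort(c2_spec, config.n_test_c2, seed=seed + 20_000)

    label_types = list(config.label_types)
    train_labels = derive_cohort_labels(train_cases, label_types, config.connectivity)
    c1_labels = derive_cohort_labels(c1_cases, label_types, config.connectivity)
    c2_lrad = derive_cohort_labels(c2_cases, ["LRad"], config.connectivity)
    rng_biopsy = np.random.default_rng(np.random.SeedSequence([seed, 555]))
    c2_eval_labels = {cid: {"LRad": biopsy_confirmed_labels(
        case, lvs["LRad"], config.c2_confirm_error, rng_biopsy)}
        for (cid, lvs), case in zip(sorted(c2_lrad.items()), c2_cases)}

    concordance = run_label_concordance(c1_cases, c1_labels, label_types,
                                        config.tasks, config.connectivity)

    fold_of = mdl.make_folds([c.case_id for c in train_cases],
                             config.n_folds, seed)
    report = {"config": to_plain(asdict(config)),
              "config_hash": config.config_hash(), "matrices": {}}
    c1_rows, c2_rows = [], []
    for arch in config.archs:
        evals_c1: dict[tuple[str, str], list[ev.PatientEval]] = {}
        evals_c2: dict[tuple[str, str], list[ev.PatientEval]] = {}
        for lt in label_types:
            preds_c1: dict[str, np.ndarray] = {}
            preds_c2: dict[str, np.ndarray] = {}
            for fold in range(config.n_folds):
                fold_cases = [c for c in train_cases
                              if config.n_folds == 1 or fold_of[c.case_id] != fold]
                tcfg = mdl.TrainConfig(arch=arch, lr=config.lr,
                                       batch_size=config.batch_size,
                                       epochs=config.epochs, n_folds=config.n_folds,
                                       seed=seed + fold, width=config.width)
                model, hist = train_label_model(fold_cases, train_labels, lt, tcfg)
                logger.info("trained %s/%s fold %d: loss %s", arch, lt, fold,
                            [round(l, 4) for l in hist.epoch_loss])
                for case in c1_cases:
                    prob, _ = predict_case(model, case)
                    preds_c1.setdefault(case.case_id, []).append(prob)
                for case in c2_cases:
                    prob, _ = predict_case(model, case)
                    preds_c2.setdefault(case.case_id, []).append(prob)
            avg = {cid: np.mean(ps, axis=0) for cid, ps in preds_c1.items()}
            avg2 = {cid: np.mean(ps, axis=0) for cid, ps in preds_c2.items()}
            for case in c1_cases:
                for evlt in label_types:
                    for task in config.tasks:
                        pe = ev.evaluate_patient(
                            avg[case.case_id], c1_labels[case.case_id][evlt],
                            case.prostate_mask, task,
                            score_statistic=config.score_statistic)
                        evals_c1.setdefault((task, lt, evlt), []).append(pe)
                        c1_rows.append(dict(cohort="C1", arch=arch,
                                            train_label=lt, eval_label=evlt,
                                            case_id=case.case_id, task=task,
                                            **_peval_row(pe)))
            for case in c2_cases:
                for task in ("cancer", "aggressive", "indolent"):
                    pe = ev.evaluate_patient(
                        avg2[case.case_id],
                        c2_eval_labels[case.case_id]["LRad"],
                        case.prostate_mask, task,
                        score_statistic=config.score_statistic)
                    evals_c2.setdefault((task, lt, "LRad"), []).append(pe)
                    c2_rows.append(dict(cohort="C2", arch=arch,
                                        train_label=lt, eval_label="LRad",
                                        case_id=case.case_id, task=task,
                                        **_peval_row(pe)))
        report["matrices"][arch] = {
            "C1": {task: ev.cross_label_matrix(
                {k[1:]: v for k, v in evals_c1.items() if k[0] == task},
                label_types, label_types) for task in config.tasks},
            "C2": {task: ev.cross_label_matrix(
                {k[1:]: v for k, v in evals_c2.items() if k[0] == task},
                label_types, ["LRad"])
                for task in ("cancer", "aggressive", "indolent")},
        }

    _write_report(out, config, concordance, report, c1_rows, c2_rows)
    report["concordance"] = concordance
    return report


def _peval_row(pe: ev.PatientEval) -> dict:
    return dict(roc_auc=pe.roc_auc, dice=pe.dice, sensitivity=pe.sensitivity,
                specificity=pe.specificity, n_pos_units=pe.n_pos_units,
                n_neg_units=pe.n_neg_units)


def _write_report(out: Path, config: StudyConfig, concordance: dict,
                  report: dict, c1_rows: list, c2_rows: list) -> None:
    (out / "config.json").write_text(
        json.dumps(to_plain(asdict(config)), indent=2, sort_keys=True))
    concordance["lesion_table"].to_csv(out / "lesion_table.csv", index=False,
                                       float_format="%.6f")
    stats = concordance["lesion_statistics"]
    if len(stats):
        stats.to_csv(out / "lesion_statistics.csv", index=False,
                     float_format="%.6f")
    for task, mats in concordance["matrices"].items():
        for metric, df in mats.items():
            df.to_csv(out / f"concordance_{task}_{metric}.csv",
                      float_format="%.6f")
    pd.DataFrame(c1_rows).to_csv(out / "per_patient_c1.csv", index=False,
                                 float_format="%.6f")
    pd.DataFrame(c2_rows).to_csv(out / "per_patient_c2.csv", index=False,
                                 float_format="%.6f")
    summary = {"config_hash": report["config_hash"], "matrices": {}}
    for arch, cohorts in report["matrices"].items():
        summary["matrices"][arch] = {}
        for cohort, tasks in cohorts.items():
            summary["matrices"][arch][cohort] = {}
            for task, mats in tasks.items():
                summary["matrices"][arch][cohort][task] = {
                    metric: json.loads(df.to_json(orient="split"))
                    for metric, df in mats.items()}
                for metric, df in mats.items():
                    df.to_csv(out / f"matrix_{arch}_{cohort}_{task}_{metric}.csv",
                              float_format="%.6f")
    (out / "report.json").write_text(json.dumps(to_plain(summary), indent=2,
                                                sort_keys=True))


def plot_matrix_heatmap(df: pd.DataFrame, title: str, path: str | Path) -> None:
    """Render a train-label x eval-label matrix as a PNG heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    data = df.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(df.index)), df.index)
    ax.set_xlabel("evaluated with")
    ax.set_ylabel("trained with")
    ax.set_title(title)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if np.isfinite(data[i, j]):
                ax.text(j, i, f"{data[i, j]:.2f}", ha="center", va="center",
                        fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
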