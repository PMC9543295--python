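"""Sextant partitioning and lesion-level detection metrics."""

import numpy as np
import pytest

from conftest import ellipsoid
from prostatelab import labels as lab
from prostatelab.evaluation import (
    DetectionRecord,
    aggregate_cohort,
    dice,
    evaluate_patient,
    label_to_probability,
    lesion_roc_auc,
    partition_sextants,
    score_units,
    sens_spec,
    task_positive_mask,
)
from prostatelab.labels import GradeMap, derive_label


def _prostate(n_slices=12, size=48):
    m = np.zeros((n_slices, size, size), bool)
    m[:, 8:size - 8, 6:size - 6] = True
    return m


# ---------------------------------------------------------------------------
# sextants
# ---------------------------------------------------------------------------

class TestSextantPartition:
    @pytest.mark.parametrize("n_slices,expected", [
        (12, (4, 4, 4)), (13, (5, 4, 4)), (14, (5, 5, 4)), (3, (1, 1, 1))])
    def test_z_thirds_with_base_first_remainder(self, n_slices, expected):
        part = partition_sextants(_prostate(n_slices))
        assert tuple(len(g) for g in part.slice_groups) == expected

    def test_exhaustive_and_disjoint_on_random_masks(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            mask = np.zeros((8, 24, 24), bool)
            # random blobby prostate spanning >= 3 slices
            n_sl = rng.integers(3, 9)
            for z in range(n_sl):
                cy, cx = rng.integers(8, 16, 2)
                mask[z] = ellipsoid((1, 24, 24), (0, cy, cx),
                                    (1, rng.integers(4, 9), rng.integers(4, 9)))[0]
            if not mask.any():
                continue
            part = partition_sextants(mask)
            ids = part.sextant_ids
            assert (ids[~mask] == 0).all()
            assert (ids[mask] > 0).all() and ids.max() <= 6
            assert ids[mask].size == mask.sum()  # every voxel exactly one region

    def test_symmetric_mask_balances_left_right(self):
        mask = _prostate(9)  # mirror-symmetric in x
        part = partition_sextants(mask)
        left = np.isin(part.sextant_ids, [1, 2, 3]).sum()
        right = np.isin(part.sextant_ids, [4, 5, 6]).sum()
        assert abs(left - right) / max(left, right) < 0.02

    def test_too_few_slices_is_an_error(self):
        with pytest.raises(ValueError, match="3 slices"):
            partition_sextants(_prostate(2))


# ---------------------------------------------------------------------------
# task masks and unit scoring
# ---------------------------------------------------------------------------

def _toy_label(with_lesion=True, lesion_class_mixed=False):
    """Small LabelVolume on a 1-mm grid with one kept lesion (512 mm^3)."""
    prostate = _prostate(6, 40)
    codes = np.where(prostate, 1, 0).astype(np.int16)
    if with_lesion:
        codes[2:4, 12:28, 10:26] = 3
        if lesion_class_mixed:
            codes[2:4, 12:28, 10:18] = 2
    gm = GradeMap(codes, (1.0, 1.0), 1.0)
    lv = derive_label(None, gm, "LPixelDPath" if lesion_class_mixed
                      else "LLesionDPath", prostate)
    return lv, prostate


class TestTaskMasks:
    def test_code_partition(self):
        lv, _ = _toy_label(lesion_class_mixed=True)
        cancer = task_positive_mask(lv, "cancer")
        agg = task_positive_mask(lv, "aggressive")
        ind = task_positive_mask(lv, "indolent")
        assert np.array_equal(cancer, agg | ind)
        assert not (agg & ind).any()
        assert agg.sum() < cancer.sum()  # mixed lesion: strict subset

    def test_all_normal_label_gives_empty_masks(self):
        lv, _ = _toy_label(with_lesion=False)
        for task in ("cancer", "aggressive", "indolent"):
            assert not task_positive_mask(lv, task).any()


class TestScoreUnits:
    def test_perfect_predictor_separates_units(self):
        lv, prostate = _toy_label()
        prob = label_to_probability(lv, prostate)
        part = partition_sextants(prostate)
        recs = score_units(prob, lv, part, "cancer", prostate)
        pos = [r for r in recs if r.truth == "positive"]
        neg = [r for r in recs if r.truth == "negative"]
        assert pos and neg
        assert all(r.score == 1.0 and r.detected for r in pos)
        assert all(r.score == 0.0 and not r.detected for r in neg)

    def test_patient_without_lesions_has_six_negative_units(self):
        lv, prostate = _toy_label(with_lesion=False)
        prob = label_to_probability(lv, prostate)
        part = partition_sextants(prostate)
        recs = score_units(prob, lv, part, "cancer", prostate)
        assert sum(r.truth == "positive" for r in recs) == 0
        assert sum(r.truth == "negative" for r in recs) == 6

    def test_constant_predictor_ties_all_scores(self):
        lv, prostate = _toy_label()
        prob = np.full((3,) + prostate.shape, 1 / 3)
        part = partition_sextants(prostate)
        recs = score_units(prob, lv, part, "cancer", prostate)
        assert len({r.score for r in recs}) == 1

    def test_unnormalized_probabilities_are_an_error(self):
        lv, prostate = _toy_label()
        prob = np.full((3,) + prostate.shape, 0.5)
        part = partition_sextants(prostate)
        with pytest.raises(ValueError, match="sum to 1"):
            score_units(prob, lv, part, "cancer", prostate)


# ---------------------------------------------------------------------------
# metrics against independent oracles
# ---------------------------------------------------------------------------

def _recs(pos_scores, neg_scores):
    return ([DetectionRecord("lesion", "positive", s, False) for s in pos_scores]
            + [DetectionRecord("sextant", "negative", s, False) for s in neg_scores])


def auc_by_pair_counting(pos, neg):
    """Brute-force AUC: fraction of (pos, neg) pairs ranked correctly."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLesionRocAuc:
    def test_canonical_values(self):
        assert lesion_roc_auc(_recs([0.9, 0.8], [0.1, 0.2])) == 1.0
        assert lesion_roc_auc(_recs([0.1, 0.2], [0.9, 0.8])) == 0.0
        assert lesion_roc_auc(_recs([0.5] * 3, [0.5] * 4)) == 0.5

    def test_undefined_without_both_classes(self):
        assert lesion_roc_auc(_recs([0.5], [])) is None
        assert lesion_roc_auc(_recs([], [0.5])) is None

    def test_matches_pair_counting_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(50):
            pos = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(1, 8))
            neg = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(1, 8))
            got = lesion_roc_auc(_recs(pos, neg))
            assert got == pytest.approx(auc_by_pair_counting(pos, neg))
            y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
            assert got == pytest.approx(roc_auc_score(y, np.r_[pos, neg]))

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.random(6), rng.random(5)
        base = lesion_roc_auc(_recs(pos, neg))
        warped = lesion_roc_auc(_recs(np.tanh(3 * pos), np.tanh(3 * neg)))
        assert base == pytest.approx(warped)

    def test_negation_with_swapped_classes_complements(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.random(6), rng.random(5)
        a = lesion_roc_auc(_recs(pos, neg))
        b = lesion_roc_auc(_recs(1 - neg, 1 - pos))
        assert a == pytest.approx(b)
        c = lesion_roc_auc(_recs(neg, pos))
        assert a == pytest.approx(1 - c)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(7)
        aucs = [lesion_roc_auc(_recs(rng.random(5), rng.random(5)))
                for _ in range(1000)]
        se = np.std(aucs, ddof=0) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-12


class TestSensSpec:
    def test_hand_enumerated_operating_point(self):
        recs = _recs([0.9, 0.6, 0.2], [0.1, 0.1, 0.3, 0.7])
        sens, spec = sens_spec(recs, 0.5)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(3 / 4)

    def test_threshold_extremes(self):
        recs = _recs([0.9, 0.6], [0.1, 0.3])
        assert sens_spec(recs, 0.0)[0] == 1.0
        sens, spec = sens_spec(recs, 1.0)
        assert sens == 0.0 and spec == 1.0

    def test_sensitivity_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(3)
        recs = _recs(rng.random(10), rng.random(10))
        senss = [sens_spec(recs, t)[0] for t in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(senss, senss[1:]))

    def test_undefined_denominators(self):
        assert sens_spec(_recs([], [0.1]), 0.5)[0] is None
        assert sens_spec(_recs([0.9], []), 0.5)[1] is None


class TestDice:
    def test_canonical_cases(self):
        a = np.zeros((2, 4, 4), bool)
        a[0, :2, :2] = a[1, :2, :2] = True  # 8-voxel cube
        assert dice(a, a) == 1.0
        b = np.roll(a, 1, axis=1)  # overlap 4 voxels
        assert dice(a, b) == pytest.approx(2 * 4 / (8 + 8))
        assert dice(a, np.zeros_like(a)) == 0.0
        assert dice(np.zeros_like(a), np.zeros_like(a)) is None

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.random((3, 8, 8)) < 0.3
            b = rng.random((3, 8, 8)) < 0.3
            if not (a.any() or b.any()):
                continue
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0 <= d <= 1


# ---------------------------------------------------------------------------
# per-patient composition and cohort aggregation
# ---------------------------------------------------------------------------

def brute_force_patient_eval(prob, lv, prostate, task):
    """Independent loop-based recomputation of the per-patient metrics."""
    chan = {"cancer": [1, 2], "aggressive": [2], "indolent": [1]}[task]
    classes = {"cancer": ("indolent", "aggressive"), "aggressive": ("aggressive",),
               "indolent": ("indolent",)}[task]
    codes = {"cancer": (2, 3), "aggressive": (3,), "indolent": (2,)}[task]
    tp = sum(prob[c] for c in chan)
    part = partition_sextants(prostate)
    hard = np.where(prostate, np.argmax(prob, axis=0) + 1, 0)
    pos, neg, det_pos, det_neg = [], [], [], []
    for les in lv.lesion_set.kept:
        if les.lesion_class in classes:
            vox = tuple(les.voxels.T)
            pos.append(tp[vox].max())
            det_pos.append(any(hard[vox][i] in codes for i in range(len(vox[0]))))
    truth = np.isin(lv.codes, codes)
    for s in range(1, 7):
        region = part.sextant_ids == s
        if region.any() and not (region & truth).any():
            neg.append(tp[region].max())
            det_neg.append(np.isin(hard[region], codes).any())
    auc = (auc_by_pair_counting(pos, neg) if pos and neg else None)
    sens = sum(det_pos) / len(det_pos) if det_pos else None
    spec = sum(not d for d in det_neg) / len(det_neg) if det_neg else None
    pred = np.isin(hard, codes)
    denom = pred.sum() + truth.sum()
    d = (2 * (pred & truth).sum() / denom) if denom else None
    return auc, d, sens, spec


class TestEvaluatePatient:
    def test_prediction_equal_to_label_is_perfect(self):
        lv, prostate = _toy_label()
        prob = label_to_probability(lv, prostate)
        pe = evaluate_patient(prob, lv, prostate, "cancer")
        assert (pe.roc_auc, pe.dice, pe.sensitivity, pe.specificity) == (1, 1, 1, 1)

    def test_all_normal_prediction_misses_everything(self):
        lv, prostate = _toy_label()
        empty, _ = _toy_label(with_lesion=False)
        prob = label_to_probability(empty, prostate)
        pe = evaluate_patient(prob, lv, prostate, "cancer")
        assert pe.sensitivity == 0.0 and pe.dice == 0.0
        assert pe.specificity == 1.0

    def test_noisy_predictor_matches_brute_force_oracle(self):
        lv, prostate = _toy_label(lesion_class_mixed=True)
        rng = np.random.default_rng(12)
        raw = rng.gamma(1.0, 1.0, size=(3,) + prostate.shape)
        prob = raw / raw.sum(axis=0, keepdims=True)
        for task in ("cancer", "aggressive", "indolent"):
            pe = evaluate_patient(prob, lv, prostate, task)
            auc, d, sens, spec = brute_force_patient_eval(prob, lv, prostate, task)
            assert pe.roc_auc == pytest.approx(auc)
            assert pe.dice == pytest.approx(d)
            assert pe.sensitivity == pytest.approx(sens)
            assert pe.specificity == pytest.approx(spec)


class TestAggregateCohort:
    def _pe(self, auc):
        from prostatelab.evaluation import PatientEval

        return PatientEval("cancer", auc, auc, auc, auc, 1, 6)

    def test_single_patient(self):
        agg = aggregate_cohort([self._pe(0.8)])
        assert agg["roc_auc"] == {"mean": 0.8, "std": 0.0, "n": 1}

    def test_population_std_convention(self):
        agg = aggregate_cohort([self._pe(1.0), self._pe(0.0)])
        assert agg["roc_auc"]["mean"] == 0.5
        assert agg["roc_auc"]["std"] == 0.5  # ddof=0

    def test_undefined_values_are_excluded_not_zeroed(self):
        agg = aggregate_cohort([self._pe(1.0), self._pe(None)])
        assert agg["roc_auc"] == {"mean": 1.0, "std": 0.0, "n": 1}
        all_undef = aggregate_cohort([self._pe(None)])
        assert all_undef["roc_auc"]["mean"] is None
        assert all_undef["roc_auc"]["n"] == 0
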