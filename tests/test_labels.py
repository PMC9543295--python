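"""Lesion formation, volume filtering and the aggressiveness classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from conftest import flood_fill_components
from prostatelab import labels as lab
from prostatelab.labels import (
    GradeMap,
    binary_close,
    classify_from_grade_group,
    classify_lesion,
    derive_label,
    filter_lesions,
    form_lesions,
    lesion_volume,
    make_structuring_element,
)


class TestStructuringElement:
    def test_pixel_radii_at_standard_resolution(self):
        el = make_structuring_element(0.29)
        # disks of 0.5, 1.5, 0.5 mm -> 2, 5, 2 pixels at 0.29 mm
        radii = []
        for k in range(3):
            ys, xs = np.nonzero(el[k])
            radii.append(int(ys.max() - el.shape[1] // 2))
        assert radii == [2, 5, 2]
        assert el.shape[0] == 3

    def test_minimum_radius_clamp(self):
        el = make_structuring_element(1.5)
        assert el.shape == (3, 3, 3)
        assert all(el[k].sum() == 5 for k in range(3))  # radius-1 disks

    def test_point_symmetry(self):
        el = make_structuring_element(0.29)
        assert np.array_equal(el, el[::-1, ::-1, ::-1])


class TestLesionVolume:
    @pytest.mark.parametrize("nl,expected", [
        (1000, 252.3), (990, 249.777), (0, 0.0)])
    def test_formula(self, nl, expected):
        assert lesion_volume(nl, 0.29, 0.29, 3.0) == pytest.approx(expected)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            lesion_volume(10, -0.29, 0.29, 3.0)


class TestFilterLesions:
    def _set(self, volumes):
        lesions = [lab.Lesion(i, np.zeros((1, 3), int), 1, v)
                   for i, v in enumerate(volumes)]
        return lab.LesionSet(kept=lesions)

    def test_threshold_semantics(self):
        out = filter_lesions(self._set([249.777, 252.3]))
        assert [l.volume_mm3 for l in out.kept] == [252.3]
        assert [l.volume_mm3 for l in out.discarded] == [249.777]

    def test_exactly_250_is_kept(self):
        out = filter_lesions(self._set([250.0]))
        assert len(out.kept) == 1 and not out.discarded

    def test_empty_set(self):
        out = filter_lesions(self._set([]))
        assert not out.kept and not out.discarded

    @given(st.lists(st.floats(min_value=0, max_value=5000,
                              allow_nan=False), max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_partition_exhaustive_and_disjoint(self, volumes):
        out = filter_lesions(self._set(volumes))
        assert len(out.kept) + len(out.discarded) == len(volumes)
        assert all(l.volume_mm3 >= 250 for l in out.kept)
        assert all(l.volume_mm3 < 250 for l in out.discarded)


class TestClassifyLesion:
    @pytest.mark.parametrize("na,ni,nl,expected", [
        (1, 0, 100, "aggressive"),
        (0, 1, 100, "indolent"),
        (0, 0, 100, "benign"),
        (0, 99, 10000, "benign"),     # just under 1 % indolent
        (100, 0, 10000, "aggressive"),  # exactly 1 %
    ])
    def test_one_percent_rule_boundaries(self, na, ni, nl, expected):
        assert classify_lesion(na, ni, nl) == expected

    def test_zero_voxels_is_an_error(self):
        with pytest.raises(ValueError):
            classify_lesion(0, 0, 0)

    @given(st.integers(1, 5000), st.data())
    @settings(deadline=None, max_examples=500)
    def test_matches_two_branch_rule_reimplementation(self, nl, data):
        na = data.draw(st.integers(0, nl))
        ni = data.draw(st.integers(0, nl - na))
        # independent re-statement of the rule
        if na >= 0.01 * nl:
            expected = "aggressive"
        elif ni >= 0.01 * nl:
            expected = "indolent"
        else:
            expected = "benign"
        assert classify_lesion(na, ni, nl) == expected


class TestGradeGroupMapping:
    @pytest.mark.parametrize("gg,expected", [
        (2, "aggressive"), (3, "aggressive"), (5, "aggressive"),
        (1, "indolent"), ("benign", "normal")])
    def test_mapping(self, gg, expected):
        assert classify_from_grade_group(gg) == expected

    @pytest.mark.parametrize("gg", [6, -1, "weird", 1.5])
    def test_out_of_range(self, gg):
        with pytest.raises(ValueError):
            classify_from_grade_group(gg)


class TestFormLesions:
    SPACING = ((0.29, 0.29), 3.0)

    def _form(self, mask, connectivity=26):
        return form_lesions(mask, self.SPACING[0], self.SPACING[1],
                            connectivity=connectivity)

    def test_closing_bridges_subkernel_gap(self):
        # Two annotation blobs separated by a single-voxel in-plane gap merge
        # into one lesion.  (Blobs must exceed the kernel footprint; a round
        # kernel never bridges isolated single voxels - standard morphology.)
        mask = np.zeros((3, 40, 40), bool)
        mask[1, 8:30, 8:11] = True
        mask[1, 8:30, 12:15] = True
        assert len(self._form(mask).kept) == 1

    def test_distant_blobs_stay_separate(self):
        mask = np.zeros((3, 128, 128), bool)
        mask[1, 20:24, 20:24] = True
        mask[1, 20:24, 89:93] = True   # 20 mm apart at 0.29 mm pixels
        assert len(self._form(mask).kept) == 2

    def test_empty_mask_yields_empty_set(self):
        out = self._form(np.zeros((3, 16, 16), bool))
        assert not out.kept and not out.discarded

    def test_closing_is_extensive_and_reduces_component_count(self):
        rng = np.random.default_rng(5)
        el = make_structuring_element(0.29)
        for _ in range(20):
            mask = rng.random((6, 16, 16)) < 0.15
            closed = binary_close(mask, el)
            assert (closed | mask).sum() == closed.sum()  # closed >= mask
            s = ndimage.generate_binary_structure(3, 3)
            assert ndimage.label(closed, s)[1] <= ndimage.label(mask, s)[1]

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_component_count_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(11)
        el = make_structuring_element(0.29)
        for _ in range(50):
            mask = rng.random((6, 16, 16)) < 0.1
            closed = binary_close(mask, el)
            got = len(self._form(mask, connectivity).kept)
            assert got == flood_fill_components(closed, connectivity)

    def test_nl_counted_on_closed_mask(self):
        mask = np.zeros((3, 40, 40), bool)
        mask[1, 8:30, 8:11] = True
        mask[1, 8:30, 12:15] = True
        les = self._form(mask).kept[0]
        assert les.NL > mask.sum()  # closing added the bridge voxels
        assert les.volume_mm3 == lesion_volume(les.NL, 0.29, 0.29, 3.0)


def _mini_grade_map(mixed=True):
    """A small grid with one mixed (or pure-GP3) lesion well above threshold."""
    codes = np.zeros((4, 40, 40), np.int16)
    prostate = np.zeros((4, 40, 40), bool)
    prostate[:, 4:36, 4:36] = True
    codes[prostate] = 1
    codes[1:3, 10:26, 10:26] = 2
    if mixed:
        codes[1:3, 14:22, 14:22] = 3
    gm = GradeMap(codes, (1.0, 1.0), 1.0)  # 1 mm voxels: lesion = 512 mm^3
    return gm, prostate


class TestDeriveLabel:
    def test_lesion_level_collapses_mixture_pixel_level_preserves_it(self):
        gm, prostate = _mini_grade_map(mixed=True)
        lesion = derive_label(None, gm, "LLesionDPath", prostate)
        pixel = derive_label(None, gm, "LPixelDPath", prostate)
        foot_l = (lesion.codes >= 2)
        foot_p = (pixel.codes >= 2)
        assert np.array_equal(foot_l, foot_p)       # identical footprints
        assert set(np.unique(lesion.codes[foot_l])) == {3}   # all aggressive
        assert {2, 3} <= set(np.unique(pixel.codes[foot_p]))  # mixture kept

    def test_radiologist_outline_over_normal_tissue_is_benign(self):
        gm, prostate = _mini_grade_map(mixed=False)
        gm.codes[gm.codes > 1] = 1  # wipe out cancer
        outline = np.zeros_like(prostate)
        outline[1:3, 8:24, 8:24] = True
        lv = derive_label(outline, gm, "LRad", prostate)
        assert not lv.lesion_set.kept
        assert set(np.unique(lv.codes)) == {0, 1}

    def test_small_lesions_are_discarded(self):
        gm, prostate = _mini_grade_map(mixed=False)
        gm.codes[gm.codes > 1] = 1
        gm.codes[1, 30:32, 30:32] = 2  # 4 mm^3 at 1 mm voxels
        lv = derive_label(None, gm, "LLesionDPath", prostate)
        assert not lv.lesion_set.kept
        assert len(lv.lesion_set.discarded) == 1

    def test_grid_mismatch_is_an_error(self):
        gm, prostate = _mini_grade_map()
        with pytest.raises(ValueError):
            derive_label(np.zeros((2, 8, 8), bool), gm, "LRad", prostate)

    def test_unknown_label_type(self):
        gm, prostate = _mini_grade_map()
        with pytest.raises(ValueError):
            derive_label(None, gm, "LFancy", prostate)


class TestPlantedClassRecovery:
    def test_derived_classes_match_planted_classes(self, desk_cohort,
                                                   desk_cohort_labels):
        """Lesion-level digital-pathologist labels recover every planted class."""
        for case in desk_cohort:
            lv = desk_cohort_labels[case.case_id]["LLesionDPath"]
            assert len(lv.lesion_set.kept) == len(case.truth_lesions)
            for les in lv.lesion_set.kept:
                overlaps = [t for t in case.truth_lesions
                            if (t.mask(case.shape)[tuple(les.voxels.T)]).any()]
                assert len(overlaps) == 1
                assert les.lesion_class == overlaps[0].lesion_class
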