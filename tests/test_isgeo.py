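"""ISGEO eye/person classification and glaucoma-type assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glaucoprev.isgeo import (
    classify_eye,
    classify_person,
    effective_vcdr,
    needs_gonioscopy,
    vcdr_asymmetry,
    vh_angle_group,
)
from glaucoprev.thresholds import published_default_thresholds
from glaucoprev.vf import VFGrade
from tests.conftest import make_eye, make_participant

TH = published_default_thresholds()


class TestBuildingBlocks:
    def test_effective_vcdr_prefers_photo(self):
        eye = make_eye(photo_vcdr=0.8, clinical_vcdr=0.6)
        assert effective_vcdr(eye) == (0.8, "image")

    def test_effective_vcdr_clinical_fallback(self):
        assert effective_vcdr(make_eye(clinical_vcdr=0.5)) == (0.5, "clinical")

    def test_effective_vcdr_absent(self):
        assert effective_vcdr(make_eye(disc_seen=False)) == (None, "none")
        assert effective_vcdr(None) == (None, "none")

    @pytest.mark.parametrize("r,l,expected", [
        (0.7, 0.6, 0.1), (0.5, None, None), (0.4, 0.4, 0.0),
    ])
    def test_asymmetry(self, r, l, expected):
        result = vcdr_asymmetry(r, l)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)

    @pytest.mark.parametrize("grade,group", [
        (0, "closure_likely"), (2, "closure_likely"),
        (3, "open"), (4, "open"),
    ])
    def test_vh_grouping(self, grade, group):
        assert vh_angle_group(grade) == group

    def test_vh_out_of_range(self):
        with pytest.raises(ValueError):
            vh_angle_group(5)

    @pytest.mark.parametrize("kwargs,fellow,expected", [
        (dict(iop_mmhg=20, clinical_vcdr=0.3, vh_grade=4), None, True),
        (dict(clinical_vcdr=0.6, vh_grade=4), None, True),
        (dict(clinical_vcdr=0.5, vh_grade=4), 0.3, True),   # asymmetry 0.2
        (dict(iop_mmhg=14, clinical_vcdr=0.3, vh_grade=2), None, True),
        (dict(iop_mmhg=14, clinical_vcdr=0.3, vh_grade=4), 0.3, False),
    ])
    def test_gonioscopy_indication(self, kwargs, fellow, expected):
        eye = make_eye(exam_level="detailed", **kwargs)
        assert needs_gonioscopy(eye, fellow) is expected


class TestClassifyEye:
    def test_structural_plus_field_is_category_1(self):
        eye = make_eye(photo_vcdr=0.70)
        dx = classify_eye(eye, None, TH, VFGrade.DEFINITE)
        assert (dx.category, dx.evidence_basis, dx.vcdr_source) == \
            ("1", "vcdr", "image")

    def test_advanced_damage_without_field_is_category_2(self):
        eye = make_eye(photo_vcdr=0.75)
        dx = classify_eye(eye, None, TH, VFGrade.NOT_USABLE)
        assert dx.category == "2"

    def test_compelling_evidence_is_category_2b(self):
        eye = make_eye(photo_vcdr=0.5, iop_mmhg=30, rapd=True)
        dx = classify_eye(eye, None, TH, VFGrade.UNLIKELY)
        assert dx.category == "2b"
        assert dx.evidence_basis == "iop_va"

    def test_end_stage_surrogate_is_category_3(self):
        eye = make_eye(disc_seen=False, presenting_va=1.78,  # 1/60
                       iop_mmhg=30)
        dx = classify_eye(eye, None, TH, VFGrade.NOT_USABLE)
        assert dx.category == "3"
        assert dx.vcdr_source == "none"

    def test_big_cup_with_normal_field_is_not_glaucoma(self):
        # category 1 needs a typical defect; category 2 needs the field to
        # be unavailable, not merely normal
        eye = make_eye(photo_vcdr=0.72)
        dx = classify_eye(eye, None, TH, VFGrade.NORMAL)
        assert not dx.glaucoma

    def test_clinical_scale_uses_clinical_cutoffs(self):
        eye = make_eye(clinical_vcdr=0.60)
        assert classify_eye(eye, None, TH, VFGrade.POSSIBLE).category == "1"
        eye2 = make_eye(photo_vcdr=0.60)
        assert not classify_eye(eye2, None, TH, VFGrade.POSSIBLE).glaucoma

    def test_asymmetry_basis(self):
        right = make_eye("R", photo_vcdr=0.55)
        left = make_eye("L", photo_vcdr=0.45)
        dx = classify_eye(right, left, TH, VFGrade.PROBABLE)
        assert (dx.category, dx.evidence_basis) == ("1", "vcdr_asymmetry")

    def test_mixed_scale_asymmetry_uses_clinical_cutoffs_and_flags(self):
        right = make_eye("R", photo_vcdr=0.55)
        left = make_eye("L", clinical_vcdr=0.40)
        dx = classify_eye(right, left, TH, VFGrade.PROBABLE)
        # |0.55-0.40| = 0.15 < clinical asym_975 of 0.20: no diagnosis
        assert not dx.glaucoma
        left2 = make_eye("L", clinical_vcdr=0.30)
        dx2 = classify_eye(right, left2, TH, VFGrade.PROBABLE)
        assert dx2.glaucoma and dx2.mixed_scale_asymmetry

    @settings(max_examples=300, derandomize=True)
    @given(v=st.sampled_from([round(0.05 * i, 2) for i in range(21)]),
           vf=st.sampled_from(list(VFGrade)),
           iop=st.sampled_from([10, 28, 40]),
           rapd=st.booleans())
    def test_raising_vcdr_never_undiagnoses(self, v, vf, iop, rapd):
        def dx(vcdr):
            eye = make_eye(photo_vcdr=vcdr, iop_mmhg=iop, rapd=rapd)
            return classify_eye(eye, None, TH, vf)

        if dx(v).glaucoma and v < 1.0:
            higher = round(v + 0.05, 2)
            d2 = dx(higher)
            # 2b is the one category that structurally requires a modest cup;
            # it can only be replaced by direct structural evidence
            assert d2.glaucoma or dx(v).category == "2b"


class TestClassifyPerson:
    def test_one_eye_suffices(self):
        p = make_participant()
        p.right_eye = make_eye("R", photo_vcdr=0.8)
        p.left_eye = make_eye("L", photo_vcdr=0.3)
        right = classify_eye(p.right_eye, p.left_eye, TH, VFGrade.DEFINITE)
        left = classify_eye(p.left_eye, p.right_eye, TH, VFGrade.NORMAL)
        dx = classify_person(right, left, p)
        assert dx.glaucoma and dx.category == "1" and dx.defining_eye == "R"

    def test_highest_evidence_wins(self):
        p = make_participant()
        p.right_eye = make_eye("R", photo_vcdr=0.75)
        p.left_eye = make_eye("L", photo_vcdr=0.70)
        right = classify_eye(p.right_eye, None, TH, VFGrade.NOT_USABLE)  # cat 2
        left = classify_eye(p.left_eye, None, TH, VFGrade.DEFINITE)     # cat 1
        dx = classify_person(right, left, p)
        assert dx.category == "1" and dx.defining_eye == "L"

    def test_no_diagnosis_means_type_not_applicable(self):
        p = make_participant()
        p.right_eye = make_eye("R", photo_vcdr=0.3)
        p.left_eye = make_eye("L", photo_vcdr=0.3)
        none_dx = classify_eye(p.right_eye, p.left_eye, TH, VFGrade.NORMAL)
        dx = classify_person(none_dx, none_dx, p)
        assert not dx.glaucoma and dx.glaucoma_type == "not_applicable"

    def test_awareness_requires_history(self):
        p = make_participant(known_glaucoma=True)
        p.right_eye = make_eye("R", photo_vcdr=0.8)
        right = classify_eye(p.right_eye, None, TH, VFGrade.DEFINITE)
        left = classify_eye(None, None, TH, VFGrade.NOT_USABLE)
        assert classify_person(right, left, p).aware


class TestClassifyType:
    def _diagnosed_person(self, **eye_kwargs):
        p = make_participant()
        p.right_eye = make_eye("R", photo_vcdr=0.8, **eye_kwargs)
        right = classify_eye(p.right_eye, None, TH, VFGrade.DEFINITE)
        left = classify_eye(None, None, TH, VFGrade.NOT_USABLE)
        return classify_person(right, left, p)

    def test_open_angle_primary(self):
        assert self._diagnosed_person(gonioscopy="open").glaucoma_type == "POAG"

    def test_closed_angle_primary(self):
        assert self._diagnosed_person(gonioscopy="closed").glaucoma_type == "PACG"

    def test_secondary_cause_overrides_angle(self):
        dx = self._diagnosed_person(gonioscopy="open",
                                    secondary_cause="couching")
        assert dx.glaucoma_type == "secondary"

    def test_no_gonioscopy_unclassified(self):
        assert self._diagnosed_person().glaucoma_type == "unclassified"


def _oracle_classify(v, vf, iop, rapd, oedema, va, surgery, known):
    """Independent truth-table reading of the case-definition grid
    (image-scale VCDR; no fellow eye, so no asymmetry route)."""
    if v is not None and v >= 0.70 and vf in ("definite", "probable",
                                              "possible"):
        return "1"
    if v is not None and v >= 0.75 and vf == "not_usable":
        return "2"
    if (v is not None and v < 0.70 and iop is not None and iop >= 28
            and (rapd or oedema) and vf != "normal"):
        return "2b"
    if v is None and vf == "not_usable":
        if surgery or known:
            return "3"
        if va is not None and va > 1.30 and iop is not None and iop >= 28:
            return "3"
    return "none"


def test_classifier_matches_truth_table_oracle():
    """Exhaustive grid comparison against a literal rule-table oracle."""
    vcdrs = [None] + [round(0.05 * i, 2) for i in range(21)]
    grades = list(VFGrade)
    count = 0
    for v in vcdrs:
        for vf in grades:
            for iop in (10, 28, 40):
                for rapd in (False, True):
                    for va in (0.0, 1.5):
                        for surgery in (False, True):
                            eye = make_eye(photo_vcdr=v,
                                           disc_seen=v is not None,
                                           iop_mmhg=iop, rapd=rapd,
                                           presenting_va=va)
                            dx = classify_eye(
                                eye, None, TH, vf,
                                glaucoma_surgery_history=surgery)
                            expected = _oracle_classify(
                                v, vf.value, iop, rapd, False, va,
                                surgery, False)
                            assert dx.category == expected, (
                                v, vf, iop, rapd, va, surgery)
                            count += 1
    assert count == 22 * 6 * 3 * 2 * 2 * 2


def test_diagnosed_persons_partition_into_types(simulated_cohort):
    """Every person counted in prevalence falls in exactly one type cell and
    the cells sum to the total."""
    from glaucoprev.pipeline import analysis_frames, classify_cohort, \
        grade_cohort_vf

    cohort, _ = simulated_cohort
    grades = grade_cohort_vf(cohort)
    person_dx, eye_dx = classify_cohort(cohort, TH, grades)
    persons, _ = analysis_frames(cohort, person_dx, eye_dx, grades)
    gl = persons[persons["glaucoma"]]
    counts = gl["glaucoma_type"].value_counts()
    assert set(counts.index) <= {"POAG", "PACG", "secondary", "unclassified"}
    assert counts.sum() == len(gl)
    assert not (persons[~persons["glaucoma"]]["glaucoma_type"]
                != "not_applicable").any()
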