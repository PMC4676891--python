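"""ISGEO glaucoma classification at eye and person level.

The International Society of Geographical and Epidemiological Ophthalmology
case definition grades the *evidence* for glaucoma rather than the disease
stage:

- Category 1: structural damage (VCDR or VCDR asymmetry at/above the
  population 97.5th percentile) together with a glaucoma-typical visual
  field defect.
- Category 2: advanced structural damage (99.5th percentile) when a useful
  visual field result was not possible or available.
- Category 2b (survey-specific addition): disc visualised with VCDR below
  the 97.5th percentile, but compelling corroboration - IOP at/above the
  99.5th percentile with an RAPD and/or corneal oedema - when fields are
  unusable or graded "unlikely" (or show a typical defect).
- Category 3: end-stage surrogate when the disc could not be seen and
  perimetry was impossible: blindness (VA worse than 3/60, i.e. <20/400)
  with IOP at/above the 99.5th percentile, or a history of glaucoma
  surgery / prior diagnosis.

Structural criteria are evaluated on the scale they were measured on:
image-based (photographic) grades use the image-scale cut-offs and clinical
(ophthalmoscopy) grades the clinical-scale ones; photographic grading takes
precedence when both exist.  A person has glaucoma if either eye does, and
carries the category of the eye with the highest level of evidence
(1 > 2 > 2b > 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .cohort import BLIND_LOGMAR, EyeExam, Participant
from .thresholds import DiagnosticThresholds
from .vf import VFGrade

__all__ = [
    "EyeDiagnosis",
    "PersonDiagnosis",
    "effective_vcdr",
    "vcdr_asymmetry",
    "classify_eye",
    "classify_person",
    "classify_type",
    "vh_angle_group",
    "needs_gonioscopy",
    "CATEGORY_ORDER",
]

#: person-level evidence ordering, most direct evidence first
CATEGORY_ORDER = ("1", "2", "2b", "3")


@dataclass(frozen=True)
class EyeDiagnosis:
    glaucoma: bool
    category: str  # "1" | "2" | "2b" | "3" | "none"
    evidence_basis: str  # "vcdr" | "vcdr_asymmetry" | "iop_va" | "history" | "none"
    vcdr_source: str  # "image" | "clinical" | "none"
    mixed_scale_asymmetry: bool = False  # asymmetry judged on clinical scale
                                         # because the two eyes used
                                         # different measurement scales

    def __post_init__(self) -> None:
        if self.glaucoma != (self.category != "none"):
            raise ValueError("glaucoma flag must match category presence")
        if self.category == "3" and self.vcdr_source != "none":
            raise ValueError("category 3 requires an unseen disc")


NO_DIAGNOSIS = EyeDiagnosis(False, "none", "none", "none")


@dataclass(frozen=True)
class PersonDiagnosis:
    glaucoma: bool
    category: str  # best eye category, or "none"
    glaucoma_type: str  # "POAG" | "PACG" | "secondary" | "unclassified" | "not_applicable"
    aware: bool
    defining_eye: str | None  # "R" | "L"


def effective_vcdr(eye: EyeExam | None) -> tuple[float | None, str]:
    """VCDR used in analysis: photographic grade if present, else clinical."""
    if eye is None:
        return None, "none"
    if eye.photo_vcdr is not None:
        return eye.photo_vcdr, "image"
    if eye.clinical_vcdr is not None:
        return eye.clinical_vcdr, "clinical"
    return None, "none"


def vcdr_asymmetry(right_value: float | None,
                   left_value: float | None) -> float | None:
    """|right - left| when both VCDRs are present, else absent."""
    if right_value is None or left_value is None:
        return None
    return abs(right_value - left_value)


def _asymmetry_with_scale(eye: EyeExam, fellow: EyeExam | None,
                          ) -> tuple[float | None, str, bool]:
    v, src = effective_vcdr(eye)
    fv, fsrc = effective_vcdr(fellow)
    asym = vcdr_asymmetry(v, fv)
    if asym is None:
        return None, "none", False
    # mixed measurement scales: judge against the clinical (wider) cut-offs
    mixed = src != fsrc
    scale = "image" if src == fsrc == "image" else "clinical"
    return asym, scale, mixed


def classify_eye(eye: EyeExam | None, fellow: EyeExam | None,
                 thresholds: DiagnosticThresholds, vf: VFGrade,
                 *, known_glaucoma: bool = False,
                 glaucoma_surgery_history: bool = False) -> EyeDiagnosis:
    """Assign the ISGEO evidence category for one eye.

    ``fellow`` is the other eye's exam (for VCDR asymmetry); ``vf`` the eye's
    visual-field grade (``NOT_USABLE`` when no reliable test exists).
    """
    if eye is None:
        return NO_DIAGNOSIS
    v, src = effective_vcdr(eye)
    asym, asym_scale, mixed = _asymmetry_with_scale(eye, fellow)

    vcdr_975 = vcdr_995 = None
    if src != "none":
        scale_th = thresholds.scale(src)
        vcdr_975, vcdr_995 = scale_th.vcdr_975, scale_th.vcdr_995
    asym_975 = asym_995 = None
    if asym is not None:
        asym_th = thresholds.scale(asym_scale)
        asym_975, asym_995 = asym_th.asym_975, asym_th.asym_995

    vcdr_at_975 = v is not None and v >= vcdr_975
    vcdr_at_995 = v is not None and v >= vcdr_995
    asym_at_975 = asym is not None and asym >= asym_975
    asym_at_995 = asym is not None and asym >= asym_995

    # Category 1: structural + functional evidence
    if (vcdr_at_975 or asym_at_975) and vf.is_typical_defect:
        basis = "vcdr" if vcdr_at_975 else "vcdr_asymmetry"
        return EyeDiagnosis(True, "1", basis, src, mixed)

    # Category 2: advanced structural damage, field result not usable
    if (vcdr_at_995 or asym_at_995) and vf is VFGrade.NOT_USABLE:
        basis = "vcdr" if vcdr_at_995 else "vcdr_asymmetry"
        return EyeDiagnosis(True, "2", basis, src, mixed)

    # Category 2b: disc seen, modest cup, compelling pressure evidence
    if (v is not None and not vcdr_at_975
            and eye.iop_mmhg is not None and eye.iop_mmhg >= thresholds.iop_995
            and (eye.rapd or eye.corneal_oedema)
            and vf is not VFGrade.NORMAL):
        return EyeDiagnosis(True, "2b", "iop_va", src, mixed)

    # Category 3: disc not seen, perimetry impossible
    if v is None and vf is VFGrade.NOT_USABLE:
        blind = (eye.presenting_va is not None
                 and eye.presenting_va > BLIND_LOGMAR)
        high_iop = (eye.iop_mmhg is not None
                    and eye.iop_mmhg >= thresholds.iop_995)
        if glaucoma_surgery_history or known_glaucoma:
            return EyeDiagnosis(True, "3", "history", "none")
        if blind and high_iop:
            return EyeDiagnosis(True, "3", "iop_va", "none")

    return NO_DIAGNOSIS


def _category_rank(category: str) -> int:
    return CATEGORY_ORDER.index(category) if category in CATEGORY_ORDER else len(CATEGORY_ORDER)


def classify_person(right: EyeDiagnosis, left: EyeDiagnosis,
                    participant: Participant) -> PersonDiagnosis:
    """Aggregate eye diagnoses: glaucoma in one or both eyes makes the person
    a case, classified by the eye with the highest level of evidence."""
    diagnosed = [(side, d) for side, d in (("R", right), ("L", left))
                 if d.glaucoma]
    if not diagnosed:
        return PersonDiagnosis(False, "none", "not_applicable", False, None)
    diagnosed.sort(key=lambda sd: (_category_rank(sd[1].category),
                                   sd[0] != "R"))
    side, best = diagnosed[0]
    if len(diagnosed) == 2 and right.category == left.category:
        # tie on evidence level: defer to the eye with the larger cup
        rv, _ = effective_vcdr(participant.right_eye)
        lv, _ = effective_vcdr(participant.left_eye)
        if rv is not None and lv is not None and lv > rv:
            side, best = "L", left
    gl_type = classify_type(
        [d for _, d in diagnosed],
        [participant.eye(s) for s, _ in diagnosed],
        defining_eye=participant.eye(side))
    return PersonDiagnosis(True, best.category, gl_type,
                           aware=participant.known_glaucoma,
                           defining_eye=side)


def classify_type(eye_diagnoses: list[EyeDiagnosis],
                  eyes: list[EyeExam | None],
                  defining_eye: EyeExam | None) -> str:
    """Glaucoma mechanism for a diagnosed person.

    A recorded secondary cause in any diagnosed eye overrides angle
    morphology; otherwise gonioscopy of the defining eye separates
    primary open-angle (open) from primary angle-closure (closed), and the
    type is unclassified when the defining eye lacks gonioscopy.
    """
    for eye in eyes:
        if eye is not None and eye.secondary_cause != "none":
            return "secondary"
    if defining_eye is None or defining_eye.gonioscopy is None:
        return "unclassified"
    return "POAG" if defining_eye.gonioscopy == "open" else "PACG"


def vh_angle_group(vh_grade: int) -> Literal["closure_likely", "open"]:
    """Van Herick grades 0-2 suggest occludable angles; 3-4 open angles."""
    if vh_grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"Van Herick grade {vh_grade!r} outside 0-4")
    return "closure_likely" if vh_grade <= 2 else "open"


def needs_gonioscopy(eye: EyeExam, fellow_vcdr: float | None = None) -> bool:
    """Gonioscopy indication at the detailed examination: IOP >= 20 mmHg, or
    VCDR >= 0.6, or VCDR asymmetry >= 0.2, or Van Herick grade 0-2."""
    v, _ = effective_vcdr(eye)
    asym = vcdr_asymmetry(v, fellow_vcdr)
    return ((eye.iop_mmhg is not None and eye.iop_mmhg >= 20)
            or (v is not None and v >= 0.6)
            or (asym is not None and asym >= 0.2)
            or (eye.vh_grade is not None and eye.vh_grade <= 2))
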