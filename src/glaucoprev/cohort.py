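"""Survey cohort data model, delimited-text I/O and validation.

Person/eye-level records from a population-based eye survey of adults aged
40+ sampled in clusters: demographics, per-eye examination findings (optic
disc grading, tonometry, anterior-chamber assessment, visual acuity) and FDT
visual-field tests.  Files are comma-separated UTF-8 with "." decimals; an
empty cell means the measurement is absent.

Visual acuity is held internally as logMAR; Snellen fractions ("6/12",
"3/60", "20/400") are converted as log10(denominator/numerator).  "Worse
than X" always means logMAR strictly greater than X's logMAR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .vf import (
    CODE_FOR_LEVEL,
    C20_GEOMETRY,
    DefectMap,
    LEVEL_CODES,
    ProbLevel,
    VFTestRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Participant",
    "EyeExam",
    "SurveyCohort",
    "ValidationIssue",
    "parse_va",
    "va_category",
    "VA_CATEGORIES",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

SECONDARY_CAUSES = (
    "none", "couching", "trauma", "uveitis", "intracapsular_surgery",
    "neovascular", "exfoliation", "pigment_dispersion", "other",
)

VA_CATEGORIES = ("normal", "mild_vi", "moderate_vi", "severe_vi", "blind")

#: logMAR upper bounds (inclusive) for each category; blind is the remainder.
#: Boundaries are half-open on the worse side: mild_vi is (0.30, 0.48],
#: i.e. worse than 6/12 but up to 6/18.
_VA_BOUNDS = (("normal", 0.30), ("mild_vi", 0.48),
              ("moderate_vi", 1.00), ("severe_vi", 1.30))

#: logMAR for "worse than 3/60" (the blindness cut-off); 20/400 is equivalent.
BLIND_LOGMAR = 1.30


def parse_va(value: float | str) -> float:
    """Parse a visual acuity as logMAR.

    Accepts a numeric logMAR value or a Snellen fraction string such as
    "6/12" or "3/60" (converted as log10(denominator/numerator) and rounded
    to two decimals, matching chart steps).
    """
    if isinstance(value, (int, float)):
        v = float(value)
        if math.isnan(v):
            raise ValueError("visual acuity is NaN")
        return v
    text = str(value).strip()
    if "/" in text:
        num_s, den_s = text.split("/", 1)
        try:
            num, den = float(num_s), float(den_s)
        except ValueError as exc:
            raise ValueError(f"unparseable Snellen acuity {value!r}") from exc
        if num <= 0 or den <= 0:
            raise ValueError(f"non-positive Snellen acuity {value!r}")
        return round(math.log10(den / num), 2)
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable visual acuity {value!r}") from exc


def va_category(presenting_va_better_eye: float | str) -> str:
    """WHO visual-status category (plus mild visual impairment) from the
    presenting acuity in the better-seeing eye.

    blind <=> acuity worse than 3/60 (logMAR > 1.30).
    """
    logmar = parse_va(presenting_va_better_eye)
    for name, bound in _VA_BOUNDS:
        if logmar <= bound:
            return name
    return "blind"


@dataclass
class EyeExam:
    """One eye's examination record.

    VCDR values live on a 0-1 scale; photographic grades are recorded to the
    nearest 0.05 and IOP to the nearest 1 mmHg.  ``presenting_va`` is logMAR.
    """

    side: str  # "R" | "L"
    photo_vcdr: float | None = None
    clinical_vcdr: float | None = None
    iop_mmhg: int | None = None
    vh_grade: int | None = None
    gonioscopy: str | None = None  # "open" | "closed"
    presenting_va: float | None = None
    secondary_cause: str = "none"
    rapd: bool = False
    corneal_oedema: bool = False
    disc_seen: bool = True
    exam_level: str = "basic"  # "basic" | "detailed"
    vf_screening: VFTestRecord | None = None
    vf_threshold: VFTestRecord | None = None

    def __post_init__(self) -> None:
        if self.side not in ("R", "L"):
            raise ValueError(f"eye side must be R or L, got {self.side!r}")
        for name in ("photo_vcdr", "clinical_vcdr"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.iop_mmhg is not None and self.iop_mmhg < 0:
            raise ValueError(f"iop_mmhg={self.iop_mmhg} negative")
        if self.vh_grade is not None and self.vh_grade not in range(5):
            raise ValueError(f"vh_grade={self.vh_grade} outside 0-4")
        if self.gonioscopy is not None and self.gonioscopy not in ("open", "closed"):
            raise ValueError(f"gonioscopy={self.gonioscopy!r} invalid")
        if self.secondary_cause not in SECONDARY_CAUSES:
            raise ValueError(f"unknown secondary cause {self.secondary_cause!r}")
        if self.exam_level not in ("basic", "detailed"):
            raise ValueError(f"exam_level={self.exam_level!r} invalid")


@dataclass
class Participant:
    person_id: str
    cluster_id: str
    age_years: int
    sex: str  # "male" | "female"
    ethnicity: str
    literate: bool
    residence: str  # "rural" | "urban"
    known_glaucoma: bool = False
    glaucoma_surgery_history: bool = False
    normative: bool = False  # member of the systematic 1-in-7 normative sample
    right_eye: EyeExam | None = None
    left_eye: EyeExam | None = None

    def __post_init__(self) -> None:
        if not self.cluster_id:
            raise ValueError(f"{self.person_id}: empty cluster_id")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.person_id}: sex={self.sex!r} invalid")
        if self.residence not in ("rural", "urban"):
            raise ValueError(f"{self.person_id}: residence={self.residence!r}")

    @property
    def eyes(self) -> list[EyeExam]:
        return [e for e in (self.right_eye, self.left_eye) if e is not None]

    def eye(self, side: str) -> EyeExam | None:
        return self.right_eye if side == "R" else self.left_eye

    @property
    def exam_level(self) -> str:
        return "detailed" if any(e.exam_level == "detailed" for e in self.eyes) \
            else "basic"

    def better_eye_va(self) -> float | None:
        vas = [e.presenting_va for e in self.eyes if e.presenting_va is not None]
        return min(vas) if vas else None

    def va_category(self) -> str | None:
        va = self.better_eye_va()
        return None if va is None else va_category(va)


@dataclass
class SurveyCohort:
    participants: dict[str, Participant] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.participants.values())

    def __len__(self) -> int:
        return len(self.participants)

    def __getitem__(self, person_id: str) -> Participant:
        return self.participants[person_id]

    def add(self, participant: Participant) -> None:
        if participant.person_id in self.participants:
            raise ValueError(f"duplicate person_id {participant.person_id!r}")
        self.participants[participant.person_id] = participant

    @property
    def n_eyes(self) -> int:
        return sum(len(p.eyes) for p in self)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

PARTICIPANT_COLUMNS = [
    "person_id", "cluster_id", "age_years", "sex", "ethnicity", "literate",
    "residence", "known_glaucoma", "glaucoma_surgery_history", "normative",
]
EYE_COLUMNS = [
    "person_id", "side", "photo_vcdr", "clinical_vcdr", "iop_mmhg",
    "vh_grade", "gonioscopy", "presenting_va", "secondary_cause", "rapd",
    "corneal_oedema", "disc_seen", "exam_level",
]
_VF_FIXED = ["person_id", "side", "mode", "fixation_errors",
             "false_positives", "lid_artefact", "untestable_reason"]


def _vf_columns(geometry=C20_GEOMETRY) -> list[str]:
    names = list(geometry.zone_names)
    return _VF_FIXED + [f"pdp_{z}" for z in names] + [f"tdp_{z}" for z in names]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _opt_float(cell) -> float | None:
    return None if cell in ("", None) or pd.isna(cell) else float(cell)


def _opt_int(cell) -> int | None:
    return None if cell in ("", None) or pd.isna(cell) else int(float(cell))


def _opt_str(cell) -> str | None:
    return None if cell in ("", None) or pd.isna(cell) else str(cell)


def _as_bool(cell) -> bool:
    if cell in ("", None) or pd.isna(cell):
        return False
    return str(cell).strip().lower() in ("1", "true", "yes")


def write_cohort(cohort: SurveyCohort, participants_path, eyes_path,
                 vf_path) -> None:
    """Write a cohort to the three CSV files (participants, eyes, VF tests)."""
    prows, erows, vrows = [], [], []
    for p in cohort:
        prows.append({
            "person_id": p.person_id, "cluster_id": p.cluster_id,
            "age_years": p.age_years, "sex": p.sex, "ethnicity": p.ethnicity,
            "literate": _fmt(p.literate), "residence": p.residence,
            "known_glaucoma": _fmt(p.known_glaucoma),
            "glaucoma_surgery_history": _fmt(p.glaucoma_surgery_history),
            "normative": _fmt(p.normative),
        })
        for eye in p.eyes:
            erows.append({
                "person_id": p.person_id, "side": eye.side,
                "photo_vcdr": _fmt(eye.photo_vcdr),
                "clinical_vcdr": _fmt(eye.clinical_vcdr),
                "iop_mmhg": _fmt(eye.iop_mmhg),
                "vh_grade": _fmt(eye.vh_grade),
                "gonioscopy": _fmt(eye.gonioscopy),
                "presenting_va": _fmt(eye.presenting_va),
                "secondary_cause": eye.secondary_cause,
                "rapd": _fmt(eye.rapd),
                "corneal_oedema": _fmt(eye.corneal_oedema),
                "disc_seen": _fmt(eye.disc_seen),
                "exam_level": eye.exam_level,
            })
            for rec in (eye.vf_screening, eye.vf_threshold):
                if rec is None:
                    continue
                row = {
                    "person_id": p.person_id, "side": eye.side,
                    "mode": rec.mode,
                    "fixation_errors": rec.fixation_errors,
                    "false_positives": rec.false_positives,
                    "lid_artefact": _fmt(rec.lid_artefact),
                    "untestable_reason": _fmt(rec.untestable_reason),
                }
                for z in C20_GEOMETRY.zone_names:
                    pdp = rec.pdp_map.level(z) if rec.pdp_map else ProbLevel.NONE
                    tdp = rec.tdp_map.level(z) if rec.tdp_map else ProbLevel.NONE
                    row[f"pdp_{z}"] = CODE_FOR_LEVEL[pdp]
                    row[f"tdp_{z}"] = CODE_FOR_LEVEL[tdp]
                vrows.append(row)
    pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS).to_csv(
        participants_path, index=False)
    pd.DataFrame(erows, columns=EYE_COLUMNS).to_csv(eyes_path, index=False)
    pd.DataFrame(vrows, columns=_vf_columns()).to_csv(vf_path, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_cohort(participants_path, eyes_path, vf_path=None) -> SurveyCohort:
    """Load a cohort from participants.csv, eyes.csv and (optional) vf.csv.

    Raises on duplicate person ids, eye rows referencing unknown persons and
    out-of-range measurements, naming the offending rows; unknown columns are
    ignored with a logged warning.
    """
    pdf = _read_csv(participants_path)
    edf = _read_csv(eyes_path)
    for name, df, known in (("participants", pdf, PARTICIPANT_COLUMNS),
                            ("eyes", edf, EYE_COLUMNS)):
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", name, unknown)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in pdf.columns
               and c != "normative"]
    missing += [c for c in EYE_COLUMNS if c not in edf.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    cohort = SurveyCohort()
    errors: list[str] = []
    for i, row in enumerate(pdf.to_dict("records")):
        try:
            cohort.add(Participant(
                person_id=str(row["person_id"]),
                cluster_id=str(row["cluster_id"]),
                age_years=int(float(row["age_years"])),
                sex=row["sex"], ethnicity=row["ethnicity"],
                literate=_as_bool(row["literate"]),
                residence=row["residence"],
                known_glaucoma=_as_bool(row["known_glaucoma"]),
                glaucoma_surgery_history=_as_bool(
                    row["glaucoma_surgery_history"]),
                normative=_as_bool(row.get("normative", "")),
            ))
        except ValueError as exc:
            errors.append(f"participants row {i + 2}: {exc}")
    for i, row in enumerate(edf.to_dict("records")):
        pid = str(row["person_id"])
        if pid not in cohort.participants:
            errors.append(f"eyes row {i + 2}: unknown person_id {pid!r}")
            continue
        try:
            va = row["presenting_va"]
            eye = EyeExam(
                side=row["side"],
                photo_vcdr=_opt_float(row["photo_vcdr"]),
                clinical_vcdr=_opt_float(row["clinical_vcdr"]),
                iop_mmhg=_opt_int(row["iop_mmhg"]),
                vh_grade=_opt_int(row["vh_grade"]),
                gonioscopy=_opt_str(row["gonioscopy"]),
                presenting_va=None if va == "" else parse_va(va),
                secondary_cause=row["secondary_cause"] or "none",
                rapd=_as_bool(row["rapd"]),
                corneal_oedema=_as_bool(row["corneal_oedema"]),
                disc_seen=_as_bool(row["disc_seen"]),
                exam_level=row["exam_level"] or "basic",
            )
        except ValueError as exc:
            errors.append(f"eyes row {i + 2}: {exc}")
            continue
        person = cohort[pid]
        if eye.side == "R":
            if person.right_eye is not None:
                errors.append(f"eyes row {i + 2}: duplicate right eye for {pid}")
                continue
            person.right_eye = eye
        else:
            if person.left_eye is not None:
                errors.append(f"eyes row {i + 2}: duplicate left eye for {pid}")
                continue
            person.left_eye = eye
    if vf_path is not None:
        _attach_vf(cohort, _read_csv(vf_path), errors)
    if errors:
        raise ValueError("cohort file errors:\n" + "\n".join(errors))
    return cohort


def _attach_vf(cohort: SurveyCohort, vdf: pd.DataFrame,
               errors: list[str]) -> None:
    zone_names = C20_GEOMETRY.zone_names
    for i, row in enumerate(vdf.to_dict("records")):
        pid = str(row["person_id"])
        if pid not in cohort.participants:
            errors.append(f"vf row {i + 2}: unknown person_id {pid!r}")
            continue
        eye = cohort[pid].eye(row["side"])
        if eye is None:
            errors.append(f"vf row {i + 2}: no eye record {pid}/{row['side']}")
            continue
        reason = _opt_str(row["untestable_reason"])
        if reason is None:
            try:
                pdp = DefectMap({z: LEVEL_CODES[str(row[f"pdp_{z}"])]
                                 for z in zone_names}, plot="PDP")
                tdp = DefectMap({z: LEVEL_CODES[str(row[f"tdp_{z}"])]
                                 for z in zone_names}, plot="TDP")
            except KeyError as exc:
                errors.append(f"vf row {i + 2}: bad level code {exc}")
                continue
        else:
            pdp = tdp = None
        rec = VFTestRecord(
            mode=row["mode"],
            fixation_errors=int(float(row["fixation_errors"])),
            false_positives=int(float(row["false_positives"])),
            pdp_map=pdp, tdp_map=tdp,
            lid_artefact=_as_bool(row["lid_artefact"]),
            untestable_reason=reason,
        )
        if rec.mode == "screening":
            eye.vf_screening = rec
        else:
            eye.vf_threshold = rec


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    person_id: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.person_id}: {self.field}: {self.rule}"


def validate_cohort(cohort: SurveyCohort) -> list[ValidationIssue]:
    """Non-mutating consistency checks; returns one issue per violated rule."""
    issues: list[ValidationIssue] = []

    def issue(pid: str, field_name: str, rule: str) -> None:
        issues.append(ValidationIssue(pid, field_name, rule))

    for p in cohort:
        if p.age_years < 40:
            issue(p.person_id, "age_years",
                  "survey enrols individuals aged 40 years and above")
        if not p.eyes:
            issue(p.person_id, "eyes",
                  "examined participant needs at least one eye record")
        for eye in p.eyes:
            tag = f"{eye.side} eye"
            if eye.photo_vcdr is not None and abs(
                    eye.photo_vcdr * 20 - round(eye.photo_vcdr * 20)) > 1e-6:
                issue(p.person_id, f"{tag} photo_vcdr",
                      "photographic VCDR is recorded to the nearest 0.05")
            if (eye.gonioscopy is not None and not eye.disc_seen
                    and eye.photo_vcdr is None and eye.clinical_vcdr is None):
                issue(p.person_id, f"{tag} gonioscopy",
                      "gonioscopy present implies a disc assessment attempt")
            if eye.gonioscopy is not None and eye.exam_level != "detailed":
                issue(p.person_id, f"{tag} gonioscopy",
                      "gonioscopy is part of the detailed examination")
            if (not eye.disc_seen
                    and (eye.photo_vcdr is not None
                         or eye.clinical_vcdr is not None)):
                issue(p.person_id, f"{tag} disc_seen",
                      "disc_seen false contradicts a recorded VCDR")
    return issues
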