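"""End-to-end orchestration: simulate/load -> grade fields -> thresholds ->
classify -> survey statistics -> agreement -> report tables.

The report bundle mirrors the bookkeeping a survey analysis publishes: a
diagnostic flow count (persons triggering the structural criteria, fields
available, persons per evidence category), an evidence tabulation
(category x basis, persons and eyes), a glaucoma-type tabulation, prevalence
tables with design-based CIs, age-standardised burden and agreement
statistics.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import agreement as agr
from . import survey
from .cohort import SurveyCohort, read_cohort, write_cohort
from .isgeo import (
    EyeDiagnosis,
    PersonDiagnosis,
    classify_eye,
    classify_person,
    effective_vcdr,
    vcdr_asymmetry,
    vh_angle_group,
)
from .simulate import SimulationConfig, generate_cohort
from .thresholds import (
    DiagnosticThresholds,
    derive_thresholds,
    load_thresholds,
    published_default_thresholds,
    save_thresholds,
)
from .vf import VFGrade, interpret_vf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "grade_cohort_vf",
           "classify_cohort", "analysis_frames", "default_standard_population"]


class RunConfig(BaseModel):
    simulation: SimulationConfig | None = None
    participants_path: str | None = None
    eyes_path: str | None = None
    vf_path: str | None = None
    thresholds_source: Literal["derive", "published_default", "file"] = "published_default"
    thresholds_path: str | None = None
    standard_population_path: str | None = None
    output_dir: str | None = None
    seed: int | None = None  # overrides the simulation seed


@dataclass
class ReportBundle:
    thresholds: DiagnosticThresholds
    persons: pd.DataFrame
    eyes: pd.DataFrame
    crude: survey.PrevalenceEstimate
    by_age: dict[str, survey.PrevalenceEstimate]
    subgroups: dict[str, dict[str, survey.PrevalenceEstimate]]
    subgroup_p: dict[str, float]
    standardized: dict
    blindness: dict
    agreement: pd.DataFrame
    flow_counts: dict
    evidence_table: pd.DataFrame
    type_table: pd.DataFrame
    truth: pd.DataFrame | None = None
    output_files: list[str] = field(default_factory=list)


def default_standard_population() -> dict[str, float]:
    """Packaged stand-in standard population (synthetic approximation of a
    national 40+ age structure; replace with an official census file for
    real analyses)."""
    path = resources.files("glaucoprev.data") / "standard_population_synthetic.csv"
    with resources.as_file(path) as p:
        return load_standard_population(p)


def load_standard_population(path) -> dict[str, float]:
    df = pd.read_csv(path)
    if not {"age_band", "population"} <= set(df.columns):
        raise ValueError("standard population needs age_band,population columns")
    return dict(zip(df["age_band"], df["population"].astype(float)))


def grade_cohort_vf(cohort: SurveyCohort) -> dict[tuple[str, str], VFGrade]:
    """Visual-field grade per (person, side)."""
    grades: dict[tuple[str, str], VFGrade] = {}
    for person in cohort:
        for eye in person.eyes:
            grades[(person.person_id, eye.side)] = interpret_vf(
                eye.vf_screening, eye.vf_threshold)
    return grades


def classify_cohort(cohort: SurveyCohort, thresholds: DiagnosticThresholds,
                    vf_grades: dict[tuple[str, str], VFGrade] | None = None,
                    ) -> tuple[dict[str, PersonDiagnosis],
                               dict[tuple[str, str], EyeDiagnosis]]:
    if vf_grades is None:
        vf_grades = grade_cohort_vf(cohort)
    person_dx: dict[str, PersonDiagnosis] = {}
    eye_dx: dict[tuple[str, str], EyeDiagnosis] = {}
    for person in cohort:
        per_side = {}
        for side in ("R", "L"):
            eye = person.eye(side)
            fellow = person.eye("L" if side == "R" else "R")
            vf = vf_grades.get((person.person_id, side), VFGrade.NOT_USABLE)
            dx = classify_eye(
                eye, fellow, thresholds, vf,
                known_glaucoma=person.known_glaucoma,
                glaucoma_surgery_history=person.glaucoma_surgery_history)
            per_side[side] = dx
            if eye is not None:
                eye_dx[(person.person_id, side)] = dx
        person_dx[person.person_id] = classify_person(
            per_side["R"], per_side["L"], person)
    return person_dx, eye_dx


def analysis_frames(cohort: SurveyCohort,
                    person_dx: dict[str, PersonDiagnosis],
                    eye_dx: dict[tuple[str, str], EyeDiagnosis],
                    vf_grades: dict[tuple[str, str], VFGrade],
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Person- and eye-level analysis tables."""
    prows, erows = [], []
    for person in cohort:
        dx = person_dx[person.person_id]
        prows.append({
            "person_id": person.person_id, "cluster_id": person.cluster_id,
            "age_years": person.age_years, "sex": person.sex,
            "ethnicity": person.ethnicity, "literate": person.literate,
            "residence": person.residence, "exam_level": person.exam_level,
            "va_category": person.va_category(),
            "glaucoma": dx.glaucoma, "category": dx.category,
            "glaucoma_type": dx.glaucoma_type, "aware": dx.aware,
            "defining_eye": dx.defining_eye or "",
        })
        for eye in person.eyes:
            d = eye_dx[(person.person_id, eye.side)]
            v, src = effective_vcdr(eye)
            erows.append({
                "person_id": person.person_id, "side": eye.side,
                "cluster_id": person.cluster_id,
                "glaucoma_eye": d.glaucoma, "category": d.category,
                "evidence_basis": d.evidence_basis, "vcdr_source": src,
                "mixed_scale_asymmetry": d.mixed_scale_asymmetry,
                "effective_vcdr": v if v is not None else np.nan,
                "photo_vcdr": eye.photo_vcdr, "clinical_vcdr": eye.clinical_vcdr,
                "iop_mmhg": eye.iop_mmhg, "vh_grade": eye.vh_grade,
                "gonioscopy": eye.gonioscopy or "",
                "presenting_va": eye.presenting_va,
                "vf_grade": vf_grades[(person.person_id, eye.side)].value,
                "exam_level": eye.exam_level,
            })
    return pd.DataFrame(prows), pd.DataFrame(erows)


def _flow_counts(cohort: SurveyCohort, thresholds: DiagnosticThresholds,
                 persons: pd.DataFrame, eyes: pd.DataFrame,
                 vf_grades: dict[tuple[str, str], VFGrade]) -> dict:
    n_examined = len(cohort)
    vcdr_trigger_persons = set()
    asym_trigger_persons = set()
    eyes_needing_vf = 0
    eyes_with_usable_vf = 0
    persons_needing = set()
    persons_with_usable = set()
    graded_eyes = 0
    photo_eyes = 0
    clinical_eyes = 0
    for person in cohort:
        rv, rsrc = effective_vcdr(person.right_eye)
        lv, lsrc = effective_vcdr(person.left_eye)
        for v, src in ((rv, rsrc), (lv, lsrc)):
            if v is not None:
                graded_eyes += 1
                if src == "image":
                    photo_eyes += 1
                else:
                    clinical_eyes += 1
        asym = vcdr_asymmetry(rv, lv)
        asym_scale = "image" if rsrc == lsrc == "image" else "clinical"
        hit_asym = asym is not None and \
            asym >= thresholds.scale(asym_scale).asym_975
        if hit_asym:
            asym_trigger_persons.add(person.person_id)
        for eye, v, src in ((person.right_eye, rv, rsrc),
                            (person.left_eye, lv, lsrc)):
            if eye is None:
                continue
            hit_vcdr = (v is not None
                        and v >= thresholds.scale(src).vcdr_975)
            if hit_vcdr:
                vcdr_trigger_persons.add(person.person_id)
            if hit_vcdr or hit_asym:
                eyes_needing_vf += 1
                persons_needing.add(person.person_id)
                if vf_grades[(person.person_id, eye.side)] is not VFGrade.NOT_USABLE:
                    eyes_with_usable_vf += 1
                    persons_with_usable.add(person.person_id)
    cat_counts = persons[persons["glaucoma"]]["category"].value_counts().to_dict()
    return {
        "persons_examined": n_examined,
        "eyes_with_disc_grade": graded_eyes,
        "eyes_photo_graded": photo_eyes,
        "eyes_clinical_graded": clinical_eyes,
        "persons_vcdr_at_975": len(vcdr_trigger_persons),
        "persons_asymmetry_at_975": len(asym_trigger_persons),
        "persons_requiring_vf": len(persons_needing),
        "eyes_requiring_vf": eyes_needing_vf,
        "persons_with_usable_vf_among_requiring": len(persons_with_usable),
        "eyes_with_usable_vf_among_requiring": eyes_with_usable_vf,
        "persons_glaucoma_total": int(persons["glaucoma"].sum()),
        "persons_by_category": {c: int(cat_counts.get(c, 0))
                                for c in ("1", "2", "2b", "3")},
    }


def _evidence_table(persons: pd.DataFrame, eyes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    gl_p = persons[persons["glaucoma"]]
    gl_e = eyes[eyes["glaucoma_eye"]]
    for cat in ("1", "2", "2b", "3"):
        for basis in sorted(gl_e[gl_e["category"] == cat]["evidence_basis"]
                            .unique()) or []:
            rows.append({
                "category": cat, "evidence_basis": basis,
                "persons": int(((gl_p["category"] == cat)
                                & (gl_p["person_id"].isin(
                                    gl_e[(gl_e["category"] == cat)
                                         & (gl_e["evidence_basis"] == basis)]
                                    ["person_id"]))).sum()),
                "eyes": int(((gl_e["category"] == cat)
                             & (gl_e["evidence_basis"] == basis)).sum()),
            })
        rows.append({"category": cat, "evidence_basis": "total",
                     "persons": int((gl_p["category"] == cat).sum()),
                     "eyes": int((gl_e["category"] == cat).sum())})
    rows.append({"category": "total", "evidence_basis": "total",
                 "persons": int(len(gl_p)), "eyes": int(len(gl_e))})
    return pd.DataFrame(rows)


def _type_table(persons: pd.DataFrame) -> pd.DataFrame:
    gl = persons[persons["glaucoma"]]
    total = len(gl)
    rows = [{"glaucoma_type": "all", "n": total, "percent": 100.0}]
    for t in ("POAG", "PACG", "secondary", "unclassified"):
        n = int((gl["glaucoma_type"] == t).sum())
        rows.append({"glaucoma_type": t, "n": n,
                     "percent": round(100.0 * n / total, 1) if total else 0.0})
    return pd.DataFrame(rows)


def _agreement_table(cohort: SurveyCohort, eyes: pd.DataFrame) -> pd.DataFrame:
    # clinical vs photographic VCDR on eyes measured both ways
    pairs = []
    for person in cohort:
        for eye in person.eyes:
            if eye.photo_vcdr is not None and eye.clinical_vcdr is not None:
                pairs.append((eye.clinical_vcdr, eye.photo_vcdr))
    rows = []
    if len(pairs) >= 2:
        kappa = agr.kappa_within_tolerance(pairs, 0.1, method="binned")
        bias, lo, hi = agr.bland_altman(pairs)
        within = agr.proportion_within(pairs, 0.25)
        rows += [
            {"statistic": "kappa_clinical_vs_image_vcdr_within_0.1",
             "value": round(kappa, 3), "n": len(pairs),
             "label": agr.kappa_label(kappa)},
            {"statistic": "bland_altman_bias", "value": round(bias, 3),
             "n": len(pairs), "label": ""},
            {"statistic": "bland_altman_lower_limit", "value": round(lo, 3),
             "n": len(pairs), "label": ""},
            {"statistic": "bland_altman_upper_limit", "value": round(hi, 3),
             "n": len(pairs), "label": ""},
            {"statistic": "pct_within_0.25", "value": round(within, 1),
             "n": len(pairs), "label": ""},
        ]
    # Van Herick grouping vs gonioscopy in glaucomatous eyes
    gl_keys = {(r.person_id, r.side)
               for r in eyes[eyes["glaucoma_eye"]].itertuples()}
    table = np.zeros((2, 2))
    for person in cohort:
        for eye in person.eyes:
            if ((person.person_id, eye.side) in gl_keys
                    and eye.vh_grade is not None and eye.gonioscopy is not None):
                i = 0 if vh_angle_group(eye.vh_grade) == "closure_likely" else 1
                j = 0 if eye.gonioscopy == "closed" else 1
                table[i, j] += 1
    n_vh = int(table.sum())
    if n_vh >= 2 and table.sum(axis=0).min() >= 0:
        kappa = agr.cohen_kappa(table)
        rows.append({"statistic": "kappa_vh_vs_gonioscopy_glaucoma_eyes",
                     "value": round(kappa, 3), "n": n_vh,
                     "label": agr.kappa_label(kappa)})
    return pd.DataFrame(rows, columns=["statistic", "value", "n", "label"])


def _resolve_thresholds(config: RunConfig, cohort: SurveyCohort,
                        vf_grades) -> DiagnosticThresholds:
    if config.thresholds_source == "published_default":
        return published_default_thresholds()
    if config.thresholds_source == "file":
        if not config.thresholds_path:
            raise ValueError("thresholds_source=file needs thresholds_path")
        return load_thresholds(config.thresholds_path)
    # derive: single pass, excluding persons who meet a glaucoma category
    # under the default cut set so diseased eyes do not shift the percentiles
    prelim_person, _ = classify_cohort(cohort, published_default_thresholds(),
                                       vf_grades)
    exclude = {pid for pid, dx in prelim_person.items() if dx.glaucoma}
    return derive_thresholds(cohort, exclude)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis; write report files when output_dir is set."""
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = sim.model_copy(update={"seed": config.seed})
        cohort, truth = generate_cohort(sim)
    else:
        if not (config.participants_path and config.eyes_path):
            raise ValueError("either a simulation config or input paths required")
        for path in (config.participants_path, config.eyes_path,
                     config.vf_path):
            if path and not Path(path).exists():
                raise FileNotFoundError(path)
        cohort = read_cohort(config.participants_path, config.eyes_path,
                             config.vf_path)
    logger.info("cohort: %d persons, %d eyes", len(cohort), cohort.n_eyes)

    vf_grades = grade_cohort_vf(cohort)
    thresholds = _resolve_thresholds(config, cohort, vf_grades)
    person_dx, eye_dx = classify_cohort(cohort, thresholds, vf_grades)
    persons, eyes = analysis_frames(cohort, person_dx, eye_dx, vf_grades)
    logger.info("diagnosed %d of %d persons with glaucoma",
                int(persons["glaucoma"].sum()), len(persons))

    crude = survey.crude_prevalence(persons)
    by_age = survey.age_specific_prevalence(persons)
    subgroups, subgroup_p = {}, {}
    for factor in survey.SUBGROUP_FACTORS:
        subgroups[factor] = survey.subgroup_prevalence(persons, factor)
        try:
            subgroup_p[factor] = survey.group_difference_test(persons, factor)
        except ValueError:
            subgroup_p[factor] = float("nan")

    std_pop = (load_standard_population(config.standard_population_path)
               if config.standard_population_path
               else default_standard_population())
    rates = {band: est.prevalence for band, est in by_age.items()}
    adjusted, burden, total_burden = survey.direct_standardize(rates, std_pop)
    standardized = {
        "age_adjusted_prevalence_pct": round(adjusted, 2),
        "burden_by_band": {b: round(v) for b, v in burden.items()},
        "total_burden": round(total_burden),
    }
    blindness = survey.blindness_summary(persons, eyes)
    agreement_df = _agreement_table(cohort, eyes)
    flow = _flow_counts(cohort, thresholds, persons, eyes, vf_grades)
    evidence = _evidence_table(persons, eyes)
    types = _type_table(persons)

    bundle = ReportBundle(
        thresholds=thresholds, persons=persons, eyes=eyes, crude=crude,
        by_age=by_age, subgroups=subgroups, subgroup_p=subgroup_p,
        standardized=standardized, blindness=blindness,
        agreement=agreement_df, flow_counts=flow, evidence_table=evidence,
        type_table=types, truth=truth)
    if config.output_dir:
        _write_bundle(bundle, cohort, config)
    return bundle


def _est_rows(estimates: dict[str, survey.PrevalenceEstimate],
              label: str) -> list[dict]:
    return [{"group": label, "level": level, **est.as_dict()}
            for level, est in estimates.items()]


def _write_bundle(bundle: ReportBundle, cohort: SurveyCohort,
                  config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        bundle.output_files.append(str(path))

    save(bundle.persons, "diagnosis.csv")
    save(bundle.eyes, "diagnosis_eyes.csv")
    prev_rows = [{"group": "total", "level": "all", **bundle.crude.as_dict()}]
    prev_rows += _est_rows(bundle.by_age, "age_band")
    save(pd.DataFrame(prev_rows), "prevalence.csv")
    sub_rows = []
    for factor, ests in bundle.subgroups.items():
        sub_rows += [{**row, "p_value": bundle.subgroup_p[factor]}
                     for row in _est_rows(ests, factor)]
    save(pd.DataFrame(sub_rows), "subgroups.csv")
    std_rows = [{"age_band": b, "burden": v}
                for b, v in bundle.standardized["burden_by_band"].items()]
    std_rows.append({"age_band": "total",
                     "burden": bundle.standardized["total_burden"]})
    save(pd.DataFrame(std_rows), "standardized.csv")
    save(bundle.agreement, "agreement.csv")
    save(bundle.evidence_table, "evidence_table.csv")
    save(bundle.type_table, "type_table.csv")
    flow_path = outdir / "flow_counts.json"
    flow_path.write_text(json.dumps({
        **bundle.flow_counts,
        "blindness": bundle.blindness,
        "standardized": bundle.standardized,
    }, indent=2))
    bundle.output_files.append(str(flow_path))
    save_thresholds(bundle.thresholds, outdir / "thresholds.yaml")
    bundle.output_files.append(str(outdir / "thresholds.yaml"))
    if bundle.truth is not None:
        bundle.truth.to_csv(outdir / "truth.csv", index=False)
        bundle.output_files.append(str(outdir / "truth.csv"))
    if config.simulation is not None:
        write_cohort(cohort, outdir / "participants.csv",
                     outdir / "eyes.csv", outdir / "vf.csv")
        bundle.output_files += [str(outdir / n) for n in
                                ("participants.csv", "eyes.csv", "vf.csv")]
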