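"""Synthetic survey cohort generator.

Emulates the statistical structure of a national cluster-sampled eye survey
of adults aged 40+: ~305 clusters of ~45 examined persons, glaucoma
prevalence rising from ~2% (40-49) to ~15% (80+) with cluster-level
heterogeneity calibrated to a design effect near 2, normal-eye IOP ~ N(14, 4)
against a trimodal IOP mixture in glaucomatous eyes (modes near 12/28/50
mmHg), photographic disc grading available for ~66% of detailed-exam eyes
with a clinical fallback for ~20.5% and no grading for ~13.5%, and usable
visual fields for ~60% of the eyes that need them.

Normal-eye VCDR is drawn from an explicit discrete distribution on the 0.05
recording grid whose 97.5th/99.5th nearest-rank percentiles sit at 0.70/0.75
on the image scale and 0.60/0.70 on the clinical scale, so that threshold
derivation from the simulated normative subsample reproduces the default cut
set.  Eyes within a person share a Gaussian-copula latent factor, giving
realistic VCDR asymmetry; the clinical grade of an eye is a noisy copy of
the same latent (plus digit preference), giving non-trivial inter-method
agreement.

Every draw flows from one seeded generator; the truth table records each
person's true status and type and which mechanisms censored each eye.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .cohort import EyeExam, Participant, SurveyCohort
from .vf import (
    C20_GEOMETRY,
    DefectMap,
    ProbLevel,
    VFTestRecord,
    needs_threshold_test,
)

__all__ = ["SimulationConfig", "generate_cohort", "generate_vf_record",
           "apply_missingness"]


# ---------------------------------------------------------------------------
# marginal distributions on the 0.05 VCDR recording grid
# ---------------------------------------------------------------------------

def _body(center: float, sd: float, upto: float, mass: float) -> dict[float, float]:
    vals = [round(0.05 * i, 2) for i in range(int(round(upto / 0.05)) + 1)]
    w = np.array([math.exp(-0.5 * ((v - center) / sd) ** 2) for v in vals])
    w = w / w.sum() * mass
    return dict(zip(vals, w))

#: normal-eye photographic VCDR: unimodal body around 0.40 with a hand-set
#: upper tail pinning the nearest-rank percentiles (97.5th -> 0.70,
#: 99.5th -> 0.75)
_IMAGE_PMF = {**_body(0.40, 0.10, 0.55, 0.915),
              0.60: 0.030, 0.65: 0.021, 0.70: 0.024,
              0.75: 0.0065, 0.80: 0.0012, 0.85: 0.0003}

#: normal-eye clinical VCDR: shifted body (ophthalmoscopy reads smaller) and
#: digit preference at 0.70; percentiles pinned at 0.60 / 0.70
_CLINICAL_PMF = {**_body(0.35, 0.10, 0.50, 0.900),
                 0.55: 0.040, 0.60: 0.045, 0.65: 0.0055,
                 0.70: 0.0085, 0.75: 0.0008, 0.80: 0.0002}


class _GridQuantile:
    """Quantile function of a discrete pmf on the VCDR grid."""

    def __init__(self, pmf: dict[float, float]):
        items = sorted(pmf.items())
        self.values = np.array([v for v, _ in items])
        w = np.array([w for _, w in items])
        self.cdf = np.cumsum(w / w.sum())

    def __call__(self, u: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.cdf, u, side="left")
        return self.values[np.clip(idx, 0, len(self.values) - 1)]


_Q_IMAGE = _GridQuantile(_IMAGE_PMF)
_Q_CLINICAL = _GridQuantile(_CLINICAL_PMF)

#: ethnic-group weights; the long tail of small groups pools as "Others" in
#: analysis (groups under 200 members)
_ETHNIC_GROUPS = (
    [("Hausa", 0.250), ("Yoruba", 0.195), ("Igbo", 0.140), ("Fulani", 0.061),
     ("Kanuri", 0.026), ("Tiv", 0.025), ("Ijaw", 0.018), ("Urhobo", 0.018),
     ("Ibibio", 0.0155), ("Nupe", 0.0155)]
    + [(f"Group{i:02d}", 0.2155 / 18) for i in range(18)]
)

#: reasons photographic grading failed, with sampling weights; the
#: eye-disease reasons co-occur with poor acuity
_NO_PHOTO_REASONS = {
    "cataract": 0.24, "corneal_opacity": 0.14, "other_ocular_pathology": 0.08,
    "uncooperative": 0.01, "other_participant_factor": 0.01,
    "faulty_camera": 0.22, "no_electricity": 0.07,
    "no_reason_stated": 0.14, "ungradable_photo": 0.10,
}
_EYE_DISEASE_REASONS = {"cataract", "corneal_opacity", "other_ocular_pathology"}

_SECONDARY_CAUSE_MIX = {
    "couching": 0.38, "trauma": 0.21, "uveitis": 0.19,
    "intracapsular_surgery": 0.17, "neovascular": 0.03,
    "exfoliation": 0.01, "pigment_dispersion": 0.01,
}


class SimulationConfig(BaseModel):
    """Study-condition parameters for the synthetic cohort."""

    n_clusters: int = 305
    persons_per_cluster: int = 45
    seed: int = 1

    #: sample age structure (share of persons per 10-year band from 40-49)
    age_band_weights: tuple[float, ...] = (0.360, 0.263, 0.204, 0.122, 0.051)
    #: true glaucoma prevalence per band, percent
    true_prevalence_by_band: tuple[float, ...] = (1.9, 3.6, 6.4, 10.8, 14.7)
    #: logit-scale cluster random-effect SD (design effect ~2 at 45/cluster)
    cluster_effect_sd: float = 0.7

    iop_normal_mean: float = 14.0
    iop_normal_sd: float = 4.0
    iop_glaucoma_means: tuple[float, ...] = (12.0, 28.0, 50.0)
    iop_glaucoma_sds: tuple[float, ...] = (3.0, 5.0, 6.0)
    iop_glaucoma_weights: tuple[float, ...] = (0.50, 0.35, 0.15)

    photo_vcdr_availability: float = 0.66
    clinical_fallback: float = 0.205
    no_disc_grade: float = 0.135
    iop_missing: float = 0.142
    vh_missing: float = 0.089
    gonioscopy_missing: float = 0.58
    vf_availability_given_needed: float = 0.60
    vf_unreliable_rate: float = 0.10

    awareness_given_glaucoma: float = 0.056
    secondary_fraction_of_glaucoma: float = 0.078
    pacg_fraction_of_primary: float = 0.14
    bilateral_fraction: float = 0.39
    #: bilateral cases in which both eyes are end-stage (blind)
    end_stage_fraction: float = 0.51
    #: blind probability for other glaucomatous eyes
    eye_blind_fraction: float = 0.20

    #: latent eye-eye correlation share (Gaussian copula weight on the
    #: person-level factor); calibrated so normative image-scale VCDR
    #: asymmetry has its 97.5th percentile at 0.10
    person_factor_share: float = 0.95
    #: copula weight tying an eye's clinical grade to its image latent
    clinical_agreement_share: float = 0.85
    #: ocular-hypertension share among non-glaucomatous eyes (raised IOP
    #: without damage; gives the normal IOP distribution its observed
    #: >21 mmHg tail)
    ocular_hypertension_fraction: float = 0.02
    ocular_hypertension_mean: float = 24.0
    ocular_hypertension_sd: float = 4.0
    #: glaucomatous eyes with early, pressure-dominant damage (cup below the
    #: structural cut-offs; only detectable via compelling-evidence criteria)
    low_vcdr_glaucoma_fraction: float = 0.02

    female_fraction: float = 0.54
    literate_fraction: float = 0.436
    rural_fraction: float = 0.775

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if abs(sum(self.age_band_weights) - 1) > 1e-6:
            raise ValueError("age_band_weights must sum to 1")
        if abs(sum(self.iop_glaucoma_weights) - 1) > 1e-6:
            raise ValueError("iop_glaucoma_weights must sum to 1")
        total = (self.photo_vcdr_availability + self.clinical_fallback
                 + self.no_disc_grade)
        if abs(total - 1) > 1e-6:
            raise ValueError("disc-grading availability mix must sum to 1")
        for name in ("photo_vcdr_availability", "clinical_fallback",
                     "no_disc_grade", "vf_availability_given_needed",
                     "awareness_given_glaucoma", "gonioscopy_missing",
                     "secondary_fraction_of_glaucoma", "vf_unreliable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        return self


_AGE_RANGES = ((40, 49), (50, 59), (60, 69), (70, 79), (80, 92))


def _round05(x: float) -> float:
    return round(round(x / 0.05) * 0.05, 2)


def _band_offsets(config: SimulationConfig) -> list[float]:
    """Logit offsets per age band so that the *marginal* prevalence matches
    the configured band value despite the convexity of the inverse logit
    under the cluster random effect (Gauss-Hermite integration)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    sd = config.cluster_effect_sd
    offsets = []
    for p in config.true_prevalence_by_band:
        target = p / 100.0
        if target <= 0.0:
            offsets.append(float("-inf"))
            continue
        base = _logit(target)

        def marginal(delta: float) -> float:
            vals = 1.0 / (1.0 + np.exp(-(base + delta + sd * nodes)))
            return float(np.sum(weights * vals) / np.sum(weights)) - target

        lo, hi = -2.0, 1.0
        for _ in range(60):  # bisection; marginal is monotone in delta
            mid = 0.5 * (lo + hi)
            if marginal(mid) > 0:
                hi = mid
            else:
                lo = mid
        offsets.append(0.5 * (lo + hi))
    return offsets


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _invlogit(x: float) -> float:
    if x < -700:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# visual-field map synthesis
# ---------------------------------------------------------------------------

def _glaucoma_map(rng: np.random.Generator, vcdr: float) -> DefectMap:
    """Clustered hemifield defects, deeper and more numerous with the cup."""
    g = C20_GEOMETRY
    k = int(np.clip(round(2 + 14 * (vcdr - 0.6) + rng.normal(0, 1.5)), 1, 12))
    hemi = "superior" if rng.random() < 0.5 else "inferior"
    zones = list(g.hemifield_zones(hemi))
    start = zones[rng.integers(len(zones))]
    chosen = {start}
    while len(chosen) < min(k, len(zones)):
        # sorted iteration keeps map growth reproducible across processes
        frontier = sorted({z for c in chosen for z in g.adjacency[c]
                           if z in zones} - chosen)
        if frontier and rng.random() < 0.8:
            chosen.add(frontier[rng.integers(len(frontier))])
        else:
            chosen.add(zones[rng.integers(len(zones))])
    levels = {}
    depth_choices = [ProbLevel.P5, ProbLevel.P2, ProbLevel.P1, ProbLevel.P05]
    for z in sorted(chosen):
        levels[z] = depth_choices[rng.choice(4, p=[0.10, 0.15, 0.30, 0.45])]
    return DefectMap(levels)


def _normal_map(rng: np.random.Generator) -> DefectMap:
    if rng.random() < 0.85:
        return DefectMap.empty()
    names = C20_GEOMETRY.zone_names
    n = 1 if rng.random() < 0.8 else 2
    levels = {}
    for z in rng.choice(len(names), size=n, replace=False):
        levels[names[z]] = ProbLevel.P2 if rng.random() < 0.03 else ProbLevel.P5
    return DefectMap(levels)


def _diffuse_tdp(rng: np.random.Generator) -> DefectMap:
    # media opacity: most zones shaded on the total-deviation plot
    names = C20_GEOMETRY.zone_names
    levels = {}
    for z in names:
        if rng.random() < 0.8:
            levels[z] = ProbLevel.P2 if rng.random() < 0.4 else ProbLevel.P5
    return DefectMap(levels, plot="TDP")


def _tdp_from_pdp(rng: np.random.Generator, pdp: DefectMap) -> DefectMap:
    # repeatable defects: TDP shows at least the PDP loss, sometimes more
    levels = dict(pdp.levels)
    if rng.random() < 0.3:
        names = C20_GEOMETRY.zone_names
        for z in rng.choice(len(names), size=rng.integers(1, 3), replace=False):
            name = names[z]
            levels[name] = max(levels.get(name, ProbLevel.NONE), ProbLevel.P5)
    return DefectMap(levels, plot="TDP")


def generate_vf_record(rng: np.random.Generator, true_glaucoma: bool,
                       vcdr: float | None, config: SimulationConfig,
                       needed: bool, cataract: bool = False,
                       va: float | None = None, full_protocol: bool = False,
                       ) -> tuple[VFTestRecord | None, VFTestRecord | None]:
    """Draw (screening, threshold) FDT records for one eye.

    Eyes whose structural findings call for field analysis lack a test with
    probability ``1 - vf_availability_given_needed``; roughly
    ``vf_unreliable_rate`` of performed tests fail the reliability indices.
    Glaucomatous eyes draw clustered hemifield defects whose number and depth
    grow with VCDR; normal eyes draw sparse isolated p<5% flags; dense
    cataract produces a diffusely shaded TDP over a clean PDP.
    """
    if (needed and not full_protocol
            and rng.random() > config.vf_availability_given_needed):
        return None, None
    # profound vision loss usually precludes seeing the flicker stimulus
    p_untestable = 0.85 if (va is not None and va > 1.3) else \
        0.25 if (va is not None and va > 0.8) else 0.02
    if rng.random() < p_untestable:
        rec = VFTestRecord("screening", 0, 0,
                           untestable_reason="could_not_see_test")
        return rec, None
    if rng.random() < config.vf_unreliable_rate:
        fe, fp = (2 + int(rng.integers(2)), int(rng.integers(4)))
    else:
        fe, fp = int(rng.integers(2)), int(rng.integers(2))
    if true_glaucoma and vcdr is not None:
        pdp = _glaucoma_map(rng, vcdr)
        tdp = _tdp_from_pdp(rng, pdp)
    elif cataract and rng.random() < 0.5:
        pdp = DefectMap.empty()
        tdp = _diffuse_tdp(rng)
    else:
        pdp = _normal_map(rng)
        tdp = _tdp_from_pdp(rng, pdp)
    screening = VFTestRecord("screening", fe, fp, pdp_map=pdp, tdp_map=tdp)

    threshold = None
    if screening.usable and needs_threshold_test(pdp) and rng.random() < 0.9:
        tfe = 3 if rng.random() < 0.05 else int(rng.integers(3))
        t_pdp = DefectMap(dict(pdp.levels))
        t_tdp = DefectMap(dict(tdp.levels), plot="TDP")
        threshold = VFTestRecord("threshold", tfe, int(rng.integers(3)),
                                 pdp_map=t_pdp, tdp_map=t_tdp)
    return screening, threshold


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_iop(rng: np.random.Generator, config: SimulationConfig,
                glaucomatous: bool) -> int:
    if glaucomatous:
        j = rng.choice(len(config.iop_glaucoma_weights),
                       p=config.iop_glaucoma_weights)
        raw = rng.normal(config.iop_glaucoma_means[j],
                         config.iop_glaucoma_sds[j])
    elif rng.random() < config.ocular_hypertension_fraction:
        raw = rng.normal(config.ocular_hypertension_mean,
                         config.ocular_hypertension_sd)
    else:
        raw = rng.normal(config.iop_normal_mean, config.iop_normal_sd)
    return max(0, int(round(raw)))


def _vh_grade(rng: np.random.Generator, closed_angle: bool) -> int:
    if closed_angle:
        return int(rng.choice(5, p=[0.30, 0.40, 0.25, 0.04, 0.01]))
    return int(rng.choice(5, p=[0.01, 0.03, 0.06, 0.40, 0.50]))


def _background_va(rng: np.random.Generator, age: int,
                   cataract_base: float | None) -> float:
    # dense bilateral media opacity shares a person-level severity; healthy
    # eyes drift with age
    if cataract_base is not None:
        return max(0.0, cataract_base + rng.normal(0, 0.2))
    return max(-0.1, rng.normal(0.05 + 0.008 * (age - 40), 0.18))


def generate_cohort(config: SimulationConfig,
                    ) -> tuple[SurveyCohort, pd.DataFrame]:
    """Simulate a fully assembled survey cohort plus its truth table.

    Deterministic for a given config (including seed).  The truth table has
    one row per person: true status and type, affected sides, and the
    censoring mechanism applied to each eye's disc grading, field test and
    gonioscopy.
    """
    rng = np.random.default_rng(config.seed)
    cohort = SurveyCohort()
    truth_rows: list[dict] = []
    ethnic_names = [n for n, _ in _ETHNIC_GROUPS]
    ethnic_w = np.array([w for _, w in _ETHNIC_GROUPS])
    ethnic_w = ethnic_w / ethnic_w.sum()
    offsets = _band_offsets(config)
    band_logits = [(_logit(p / 100.0) + d if p > 0 else float("-inf"))
                   for p, d in zip(config.true_prevalence_by_band, offsets)]

    person_counter = 0
    for c in range(config.n_clusters):
        cluster_id = f"C{c + 1:04d}"
        u_c = rng.normal(0, config.cluster_effect_sd)
        for _ in range(config.persons_per_cluster):
            person_counter += 1
            pid = f"P{person_counter:06d}"
            band = int(rng.choice(5, p=config.age_band_weights))
            lo, hi = _AGE_RANGES[band]
            age = int(rng.integers(lo, hi + 1))
            sex = "female" if rng.random() < config.female_fraction else "male"
            ethnicity = ethnic_names[int(rng.choice(len(ethnic_w), p=ethnic_w))]
            literate = rng.random() < config.literate_fraction
            residence = "rural" if rng.random() < config.rural_fraction else "urban"
            normative = person_counter % 7 == 0

            p_true = _invlogit(band_logits[band] + u_c)
            true_glaucoma = rng.random() < p_true
            bilateral = bool(true_glaucoma
                             and rng.random() < config.bilateral_fraction)
            if true_glaucoma:
                affected = {"R", "L"} if bilateral else \
                    ({"R"} if rng.random() < 0.5 else {"L"})
                if rng.random() < config.secondary_fraction_of_glaucoma:
                    true_type = "secondary"
                elif rng.random() < config.pacg_fraction_of_primary:
                    true_type = "PACG"
                else:
                    true_type = "POAG"
            else:
                affected, true_type = set(), "none"
            known = bool(true_glaucoma
                         and rng.random() < config.awareness_given_glaucoma)
            surgery = bool(known and rng.random() < 0.5)
            end_stage = bool(bilateral and rng.random() < config.end_stage_fraction)
            closed_angle = true_type == "PACG"
            secondary_cause = None
            if true_type == "secondary":
                causes = list(_SECONDARY_CAUSE_MIX)
                w = np.array(list(_SECONDARY_CAUSE_MIX.values()))
                secondary_cause = causes[int(rng.choice(len(w), p=w / w.sum()))]

            cataract_base = (rng.uniform(0.8, 2.6)
                             if rng.random() < min(0.01 + 0.002 * (age - 40),
                                                   0.15) else None)
            z_person = rng.normal()
            share = math.sqrt(config.person_factor_share)
            resid = math.sqrt(1 - config.person_factor_share)
            cshare = config.clinical_agreement_share

            eyes: dict[str, dict] = {}
            for side in ("R", "L"):
                z_eye = share * z_person + resid * rng.normal()
                glaucomatous = side in affected
                if glaucomatous:
                    if rng.random() < config.low_vcdr_glaucoma_fraction:
                        true_vcdr = _round05(rng.uniform(0.40, 0.65))
                    else:
                        true_vcdr = _round05(0.65 + 0.35 * rng.beta(3.0, 1.0))
                    clin = _round05(np.clip(
                        true_vcdr - 0.025 + rng.normal(0, 0.05), 0.0, 1.0))
                else:
                    true_vcdr = float(_Q_IMAGE(
                        0.5 * (1 + math.erf(z_eye / math.sqrt(2)))))
                    z_clin = cshare * z_eye + math.sqrt(1 - cshare ** 2) * rng.normal()
                    clin = float(_Q_CLINICAL(
                        0.5 * (1 + math.erf(z_clin / math.sqrt(2)))))
                va = _background_va(rng, age, cataract_base)
                if glaucomatous:
                    if end_stage or rng.random() < config.eye_blind_fraction:
                        va = max(va, rng.uniform(1.4, 2.5))
                    else:
                        va += rng.uniform(0, 0.6)
                eyes[side] = {"glaucomatous": glaucomatous,
                              "true_vcdr": true_vcdr, "clinical": clin,
                              "va": round(va, 2)}

            detailed = (
                normative
                or any(e["va"] > 0.30 for e in eyes.values())
                or any(e["clinical"] >= 0.60 for e in eyes.values())
                or abs(eyes["R"]["clinical"] - eyes["L"]["clinical"]) >= 0.2
            )
            exam_level = "detailed" if detailed else "basic"

            participant = Participant(
                person_id=pid, cluster_id=cluster_id, age_years=age, sex=sex,
                ethnicity=ethnicity, literate=literate, residence=residence,
                known_glaucoma=known, glaucoma_surgery_history=surgery,
                normative=normative,
            )
            truth = {
                "person_id": pid, "cluster_id": cluster_id,
                "true_glaucoma": true_glaucoma, "true_type": true_type,
                "bilateral": bilateral,
                "affected_eyes": "".join(sorted(affected)),
            }
            for side in ("R", "L"):
                info = eyes[side]
                exam = EyeExam(
                    side=side,
                    photo_vcdr=info["true_vcdr"] if detailed else None,
                    clinical_vcdr=info["clinical"],
                    iop_mmhg=_sample_iop(rng, config, info["glaucomatous"])
                    if detailed else None,
                    vh_grade=_vh_grade(rng, closed_angle and info["glaucomatous"])
                    if detailed else None,
                    presenting_va=info["va"],
                    secondary_cause=(secondary_cause
                                     if info["glaucomatous"] and secondary_cause
                                     else "none"),
                    rapd=rng.random() < (0.25 if info["glaucomatous"] else 0.01)
                    if detailed else False,
                    corneal_oedema=rng.random()
                    < (0.02 if info["glaucomatous"] else 0.002)
                    if detailed else False,
                    disc_seen=True,
                    exam_level=exam_level,
                )
                truth[f"{side}_true_glaucoma"] = info["glaucomatous"]
                truth[f"{side}_true_vcdr"] = info["true_vcdr"]
                if side == "R":
                    participant.right_eye = exam
                else:
                    participant.left_eye = exam
            cohort.add(participant)
            truth_rows.append(truth)

    truth_df = pd.DataFrame(truth_rows)
    censor_df = apply_missingness(cohort, config, truth_df)
    truth_df = truth_df.merge(censor_df, on="person_id", how="left")
    _attach_vf_tests(cohort, config, truth_df)
    return cohort, truth_df


def apply_missingness(cohort: SurveyCohort, config: SimulationConfig,
                      truth_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Censor the fully observed cohort in place.

    Detailed-exam eyes keep their photographic grade with probability
    ``photo_vcdr_availability``, fall back to the clinical grade with
    ``clinical_fallback`` and lose the disc grading altogether with
    ``no_disc_grade`` (reason codes mirror field conditions: eye disease,
    participant factors, camera/electricity faults, ungradable images; the
    eye-disease reasons co-occur with poor acuity).  IOP, Van Herick grading
    and gonioscopy are thinned at their own rates.  Returns one censoring row
    per person.
    """
    rng = np.random.default_rng([config.seed, 7])
    reasons = list(_NO_PHOTO_REASONS)
    base_w = np.array(list(_NO_PHOTO_REASONS.values()))
    base_w = base_w / base_w.sum()
    disease_mask = np.array([r in _EYE_DISEASE_REASONS for r in reasons])
    disease_w = np.where(disease_mask, base_w * 2.5, base_w)
    disease_w = disease_w / disease_w.sum()

    # Dense media opacity blocks any disc view, so blind eyes lose grading
    # more often; the non-blind rate is solved so the marginal no-grade
    # fraction stays at the configured value.
    detailed_eyes = [e for p in cohort for e in p.eyes
                     if e.exam_level == "detailed"]
    blind_frac = (np.mean([e.presenting_va is not None
                           and e.presenting_va > 1.3 for e in detailed_eyes])
                  if detailed_eyes else 0.0)
    m = config.no_disc_grade
    p_none_blind = min(1.0, 2.6 * m)
    if blind_frac > 0 and blind_frac * p_none_blind > m:
        p_none_blind = m / blind_frac
    p_none_clear = max(0.0, (m - blind_frac * p_none_blind)
                       / max(1.0 - blind_frac, 1e-9))

    rows = []
    for person in cohort:
        row = {"person_id": person.person_id}
        # camera/electricity failures and participant factors hit both eyes
        # of a person together: share one uniform draw between the eyes
        u_shared = rng.random()
        share_draw = rng.random() < 0.45
        for eye in person.eyes:
            tag = f"{eye.side}_photo_censor"
            row[tag] = ""
            row[f"{eye.side}_gonio_censored"] = False
            if eye.exam_level != "detailed":
                continue
            u = u_shared if share_draw else rng.random()
            blind_eye = eye.presenting_va is not None and eye.presenting_va > 1.3
            bad_va = eye.presenting_va is not None and eye.presenting_va > 0.8
            w = disease_w if bad_va else base_w
            p_none = p_none_blind if blind_eye else p_none_clear
            if u < p_none:
                reason = reasons[int(rng.choice(len(w), p=w))]
                eye.photo_vcdr = None
                eye.clinical_vcdr = None
                eye.disc_seen = False
                row[tag] = f"none:{reason}"
                if reason in _EYE_DISEASE_REASONS and eye.presenting_va is not None:
                    eye.presenting_va = round(
                        max(eye.presenting_va, rng.uniform(0.8, 2.2)), 2)
            elif u < p_none + config.clinical_fallback:
                reason = reasons[int(rng.choice(len(w), p=w))]
                eye.photo_vcdr = None
                row[tag] = f"clinical:{reason}"
            else:
                # photographic grade kept; clinical grade co-recorded for
                # most eyes (the agreement-study pairs)
                if rng.random() > 0.9:
                    eye.clinical_vcdr = None
            if eye.iop_mmhg is not None and rng.random() < config.iop_missing:
                eye.iop_mmhg = None
            if eye.vh_grade is not None and rng.random() < config.vh_missing:
                eye.vh_grade = None
        rows.append(row)
    _assign_gonioscopy(cohort, config, rng, rows, truth_df)
    return pd.DataFrame(rows)


def _assign_gonioscopy(cohort: SurveyCohort, config: SimulationConfig,
                       rng: np.random.Generator, rows: list[dict],
                       truth_df: pd.DataFrame | None) -> None:
    # gonioscopy only where indicated, thinned by lens damage in the field;
    # the result reflects the true angle status (narrow angles in
    # angle-closure disease, rarely otherwise)
    from .isgeo import effective_vcdr, needs_gonioscopy

    closed_lookup: dict[tuple[str, str], bool] = {}
    if truth_df is not None:
        for r in truth_df.itertuples():
            for side in ("R", "L"):
                closed_lookup[(r.person_id, side)] = (
                    r.true_type == "PACG"
                    and getattr(r, f"{side}_true_glaucoma"))
    row_by_pid = {r["person_id"]: r for r in rows}
    for person in cohort:
        row = row_by_pid[person.person_id]
        for eye in person.eyes:
            if eye.exam_level != "detailed" or not eye.disc_seen:
                # dense media opacity blocks the gonioscopy view as well
                continue
            fellow = person.eye("L" if eye.side == "R" else "R")
            fv, _ = effective_vcdr(fellow)
            if not needs_gonioscopy(eye, fv):
                continue
            if rng.random() < config.gonioscopy_missing:
                row[f"{eye.side}_gonio_censored"] = True
                continue
            truly_closed = closed_lookup.get(
                (person.person_id, eye.side),
                eye.vh_grade is not None and eye.vh_grade <= 2)
            closed = rng.random() < (0.90 if truly_closed else 0.03)
            eye.gonioscopy = "closed" if closed else "open"


def _attach_vf_tests(cohort: SurveyCohort, config: SimulationConfig,
                     truth_df: pd.DataFrame) -> None:
    from .isgeo import effective_vcdr, vcdr_asymmetry

    rng = np.random.default_rng([config.seed, 11])
    truth = truth_df.set_index("person_id")
    for person in cohort:
        trow = truth.loc[person.person_id]
        rv, rsrc = effective_vcdr(person.right_eye)
        lv, lsrc = effective_vcdr(person.left_eye)
        asym = vcdr_asymmetry(rv, lv)
        asym_scale_clinical = rsrc != lsrc or rsrc == "clinical"
        asym_needed = asym is not None and (
            asym >= (0.2 if asym_scale_clinical else 0.1))
        for eye in person.eyes:
            v, src = effective_vcdr(eye)
            needed = asym_needed or (
                v is not None and v >= (0.60 if src == "clinical" else 0.70))
            glaucomatous = bool(trow[f"{eye.side}_true_glaucoma"])
            cataract = (not glaucomatous and eye.presenting_va is not None
                        and eye.presenting_va > 0.8)
            screening, threshold = generate_vf_record(
                rng, glaucomatous, trow[f"{eye.side}_true_vcdr"],
                config, needed, cataract, va=eye.presenting_va,
                full_protocol=person.normative)
            eye.vf_screening = screening
            eye.vf_threshold = threshold
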