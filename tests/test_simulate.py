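"""Synthetic cohort generator: determinism, calibration, censoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from glaucoprev.simulate import SimulationConfig, generate_cohort, \
    generate_vf_record
from glaucoprev.vf import VFGrade, interpret_vf


SMALL = dict(n_clusters=20, persons_per_cluster=45)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        c1, t1 = generate_cohort(SimulationConfig(seed=99, **SMALL))
        c2, t2 = generate_cohort(SimulationConfig(seed=99, **SMALL))
        assert c1.participants == c2.participants
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        c1, _ = generate_cohort(SimulationConfig(seed=1, **SMALL))
        c2, _ = generate_cohort(SimulationConfig(seed=2, **SMALL))
        assert c1.participants != c2.participants


class TestTruth:
    def test_zero_prevalence_no_true_cases(self):
        cfg = SimulationConfig(seed=3, n_clusters=10, persons_per_cluster=30,
                               true_prevalence_by_band=(0, 0, 0, 0, 0))
        _, truth = generate_cohort(cfg)
        assert truth.true_glaucoma.sum() == 0
        assert (truth.true_type == "none").all()

    def test_truth_covers_every_person(self, simulated_cohort):
        cohort, truth = simulated_cohort
        assert set(truth.person_id) == set(cohort.participants)
        gl = truth[truth.true_glaucoma]
        assert (gl.affected_eyes != "").all()
        assert gl.true_type.isin(["POAG", "PACG", "secondary"]).all()

    def test_higher_band_prevalence_means_more_cases(self):
        lo = SimulationConfig(seed=8, **SMALL,
                              true_prevalence_by_band=(1, 2, 3, 4, 5))
        hi = SimulationConfig(seed=8, **SMALL,
                              true_prevalence_by_band=(5, 10, 15, 20, 25))
        _, t_lo = generate_cohort(lo)
        _, t_hi = generate_cohort(hi)
        assert t_hi.true_glaucoma.sum() > t_lo.true_glaucoma.sum()


class TestCalibration:
    def test_marginal_prevalence_near_configured(self):
        cfg = SimulationConfig(seed=10, n_clusters=150, persons_per_cluster=45)
        _, truth = generate_cohort(cfg)
        # expected marginal = age-weighted band prevalences = 5.0%
        expected = sum(w * p for w, p in zip(cfg.age_band_weights,
                                             cfg.true_prevalence_by_band))
        assert truth.true_glaucoma.mean() * 100 == pytest.approx(
            expected, abs=0.8)

    def test_nonglaucoma_iop_tail(self, simulated_cohort):
        """Recorded IOP > 21 mmHg in non-glaucomatous eyes matches the
        analytic tail of the configured mixture (integer recording means
        the event is {raw > 21.5})."""
        cohort, truth = simulated_cohort
        cfg = SimulationConfig()
        t = truth.set_index("person_id")
        iops = []
        for person in cohort:
            for eye in person.eyes:
                if eye.iop_mmhg is not None and not bool(
                        t.loc[person.person_id, f"{eye.side}_true_glaucoma"]):
                    iops.append(eye.iop_mmhg)
        frac = np.mean([v > 21 for v in iops])
        w = cfg.ocular_hypertension_fraction
        analytic = ((1 - w) * norm.sf(21.5, cfg.iop_normal_mean,
                                      cfg.iop_normal_sd)
                    + w * norm.sf(21.5, cfg.ocular_hypertension_mean,
                                  cfg.ocular_hypertension_sd))
        assert frac == pytest.approx(analytic, abs=0.012)

    def test_glaucoma_iop_mixture_mean(self, simulated_cohort):
        cohort, truth = simulated_cohort
        t = truth.set_index("person_id")
        iops = [eye.iop_mmhg for person in cohort for eye in person.eyes
                if eye.iop_mmhg is not None
                and bool(t.loc[person.person_id,
                               f"{eye.side}_true_glaucoma"])]
        assert np.mean(iops) == pytest.approx(23.3, abs=2.0)


class TestMissingness:
    def test_no_disc_grade_fraction(self, simulated_cohort):
        cohort, _ = simulated_cohort
        detailed = [e for p in cohort for e in p.eyes
                    if e.exam_level == "detailed"]
        none_frac = np.mean([e.photo_vcdr is None and e.clinical_vcdr is None
                             for e in detailed])
        assert none_frac == pytest.approx(0.135, abs=0.015)

    def test_photo_fraction(self, simulated_cohort):
        cohort, _ = simulated_cohort
        detailed = [e for p in cohort for e in p.eyes
                    if e.exam_level == "detailed"]
        photo_frac = np.mean([e.photo_vcdr is not None for e in detailed])
        assert photo_frac == pytest.approx(0.66, abs=0.02)

    def test_full_availability_no_censoring(self):
        cfg = SimulationConfig(seed=4, n_clusters=10, persons_per_cluster=30,
                               photo_vcdr_availability=1.0,
                               clinical_fallback=0.0, no_disc_grade=0.0)
        cohort, _ = generate_cohort(cfg)
        for person in cohort:
            for eye in person.eyes:
                if eye.exam_level == "detailed":
                    assert eye.photo_vcdr is not None

    def test_all_censored_forces_category_3_or_none(self):
        """With every detailed-exam disc grade censored, any diagnosis can
        only arrive through the end-stage surrogate category."""
        from glaucoprev.pipeline import classify_cohort
        from glaucoprev.thresholds import published_default_thresholds

        cfg = SimulationConfig(seed=6, n_clusters=15, persons_per_cluster=45,
                               photo_vcdr_availability=0.0,
                               clinical_fallback=0.0, no_disc_grade=1.0)
        cohort, _ = generate_cohort(cfg)
        person_dx, eye_dx = classify_cohort(cohort,
                                            published_default_thresholds())
        assert {dx.category for dx in person_dx.values()} <= {"3", "none"}


class TestVFGeneration:
    def test_normal_eye_rarely_abnormal(self, rng):
        cfg = SimulationConfig()
        graded = []
        for _ in range(1000):
            s, t = generate_vf_record(rng, False, None, cfg, needed=False)
            grade = interpret_vf(s, t)
            if grade is not VFGrade.NOT_USABLE:
                graded.append(grade)
        normal_frac = np.mean([g is VFGrade.NORMAL for g in graded])
        assert normal_frac >= 0.90

    def test_severe_glaucoma_mostly_definite(self, rng):
        cfg = SimulationConfig()
        graded = []
        for _ in range(500):
            s, t = generate_vf_record(rng, True, 0.9, cfg, needed=False)
            grade = interpret_vf(s, t)
            if grade is not VFGrade.NOT_USABLE:
                graded.append(grade)
        definite_frac = np.mean([g is VFGrade.DEFINITE for g in graded])
        assert definite_frac > 0.6

    def test_zero_availability_means_absent_when_needed(self, rng):
        cfg = SimulationConfig(vf_availability_given_needed=0.0)
        for _ in range(50):
            assert generate_vf_record(rng, False, None, cfg,
                                      needed=True) == (None, None)
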