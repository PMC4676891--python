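import numpy as np
import pytest

from glaucoprev.cohort import EyeExam, Participant, SurveyCohort
from glaucoprev.simulate import SimulationConfig, generate_cohort
from glaucoprev.vf import C20_GEOMETRY, DefectMap, ProbLevel


def make_eye(side="R", **kwargs) -> EyeExam:
    return EyeExam(side=side, **kwargs)


def make_participant(pid="P1", cluster="C1", age=55, **kwargs) -> Participant:
    defaults = dict(sex="female", ethnicity="Hausa", literate=True,
                    residence="rural")
    defaults.update(kwargs)
    return Participant(person_id=pid, cluster_id=cluster, age_years=age,
                       **defaults)


def pdp_of(levels: dict[str, ProbLevel]) -> DefectMap:
    return DefectMap(dict(levels), C20_GEOMETRY, plot="PDP")


def tdp_like(pdp: DefectMap) -> DefectMap:
    return DefectMap(dict(pdp.levels), pdp.geometry, plot="TDP")


@pytest.fixture(scope="session")
def small_cohort() -> SurveyCohort:
    cohort = SurveyCohort()
    for i, (age, sex) in enumerate([(45, "male"), (62, "female"),
                                    (81, "female")], 1):
        p = make_participant(pid=f"P{i}", cluster=f"C{1 + i % 2}", age=age,
                             sex=sex)
        p.right_eye = make_eye("R", clinical_vcdr=0.4, presenting_va=0.1)
        p.left_eye = make_eye("L", clinical_vcdr=0.45, presenting_va=0.2)
        cohort.add(p)
    return cohort


@pytest.fixture(scope="session")
def simulated_cohort():
    """Mid-sized synthetic cohort shared across tests (deterministic)."""
    config = SimulationConfig(n_clusters=60, persons_per_cluster=45, seed=424)
    return generate_cohort(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260)
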