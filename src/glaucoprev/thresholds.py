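"""Population-specific diagnostic cut-offs for VCDR, VCDR asymmetry and IOP.

Epidemiological glaucoma case definitions anchor their structural criteria to
the 97.5th and 99.5th percentiles of vertical cup:disc ratio (and asymmetry)
and the 99.5th percentile of IOP in the *normal* population under study,
rather than to fixed clinical cut-offs.  This module derives those
percentiles from a normative subsample (the systematic 1-in-7 detailed-exam
sample) with a nearest-rank percentile, and also provides the published cut
set as a constant.

Nearest-rank (no interpolation) is deliberate: VCDR is recorded on a 0.05
grid and IOP on a 1 mmHg grid, so interpolation would fabricate values that
cannot be observed.
"""

from __future__ import annotations

import logging
import math
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, model_validator

from .cohort import SurveyCohort

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleThresholds",
    "DiagnosticThresholds",
    "published_default_thresholds",
    "percentile",
    "derive_thresholds",
    "load_thresholds",
    "save_thresholds",
]


class ScaleThresholds(BaseModel):
    """Cut-offs on one VCDR measurement scale (image-based or clinical)."""

    vcdr_975: float
    vcdr_995: float
    asym_975: float
    asym_995: float

    @model_validator(mode="after")
    def _ordered(self) -> "ScaleThresholds":
        if self.vcdr_975 > self.vcdr_995:
            raise ValueError("vcdr_975 must not exceed vcdr_995")
        if self.asym_975 > self.asym_995:
            raise ValueError("asym_975 must not exceed asym_995")
        for name in ("vcdr_975", "vcdr_995", "asym_975", "asym_995"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        return self


class DiagnosticThresholds(BaseModel):
    image: ScaleThresholds
    clinical: ScaleThresholds
    iop_995: float
    source: Literal["derived", "published_default", "file"] = "derived"

    def scale(self, vcdr_source: str) -> ScaleThresholds:
        if vcdr_source == "image":
            return self.image
        if vcdr_source == "clinical":
            return self.clinical
        raise ValueError(f"no thresholds for vcdr source {vcdr_source!r}")


def published_default_thresholds() -> DiagnosticThresholds:
    """The published cut set for this survey population.

    Image scale: VCDR 0.70 / 0.75 and asymmetry 0.10 / 0.20 at the 97.5th /
    99.5th percentiles; clinical scale: VCDR 0.60 / 0.70 and asymmetry
    0.20 / 0.30; IOP 28 mmHg at the 99.5th percentile.
    """
    return DiagnosticThresholds(
        image=ScaleThresholds(vcdr_975=0.70, vcdr_995=0.75,
                              asym_975=0.10, asym_995=0.20),
        clinical=ScaleThresholds(vcdr_975=0.60, vcdr_995=0.70,
                                 asym_975=0.20, asym_995=0.30),
        iop_995=28,
        source="published_default",
    )


def percentile(values: Sequence[float], p: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p/100 * n) of the
    sorted list (1-based)."""
    if len(values) == 0:
        raise ValueError("percentile of an empty list is undefined")
    if not 0.0 < p < 100.0:
        raise ValueError(f"percentile p={p} outside (0, 100)")
    ordered = sorted(values)
    rank = math.ceil(p / 100.0 * len(ordered))
    return ordered[rank - 1]


def derive_thresholds(cohort: SurveyCohort,
                      exclude_person_ids: frozenset[str] | set[str] = frozenset(),
                      ) -> DiagnosticThresholds:
    """Derive the percentile cut-offs from a cohort's normative subsample.

    Uses participants flagged ``normative`` (the systematic 1-in-7 sample),
    minus ``exclude_person_ids`` (typically persons meeting a glaucoma
    category under the default cut set, so that diseased eyes do not drag the
    normal percentiles).  The image and clinical scales are parallel
    distributions: each asymmetry is computed from same-scale pairs of eyes.
    Raises if any required measure has no observations, naming the measure.
    """
    image_vcdr: list[float] = []
    clinical_vcdr: list[float] = []
    image_asym: list[float] = []
    clinical_asym: list[float] = []
    iops: list[float] = []
    n_persons = 0
    for person in cohort:
        if not person.normative or person.person_id in exclude_person_ids:
            continue
        n_persons += 1
        photo_pair: list[float] = []
        clin_pair: list[float] = []
        for eye in person.eyes:
            if eye.photo_vcdr is not None:
                image_vcdr.append(eye.photo_vcdr)
                photo_pair.append(eye.photo_vcdr)
            if eye.clinical_vcdr is not None:
                clinical_vcdr.append(eye.clinical_vcdr)
                clin_pair.append(eye.clinical_vcdr)
            if eye.iop_mmhg is not None:
                iops.append(eye.iop_mmhg)
        if len(photo_pair) == 2:
            image_asym.append(abs(photo_pair[0] - photo_pair[1]))
        if len(clin_pair) == 2:
            clinical_asym.append(abs(clin_pair[0] - clin_pair[1]))
    for name, vals in (("image VCDR", image_vcdr),
                       ("clinical VCDR", clinical_vcdr),
                       ("image VCDR asymmetry", image_asym),
                       ("clinical VCDR asymmetry", clinical_asym),
                       ("IOP", iops)):
        if not vals:
            raise ValueError(f"normative subsample has no {name} observations")
    logger.info(
        "normative thresholds derived from %d persons "
        "(image VCDR n=%d, clinical VCDR n=%d, image asym n=%d, "
        "clinical asym n=%d, IOP n=%d)",
        n_persons, len(image_vcdr), len(clinical_vcdr), len(image_asym),
        len(clinical_asym), len(iops))
    return DiagnosticThresholds(
        image=ScaleThresholds(
            vcdr_975=percentile(image_vcdr, 97.5),
            vcdr_995=percentile(image_vcdr, 99.5),
            asym_975=percentile(image_asym, 97.5),
            asym_995=percentile(image_asym, 99.5)),
        clinical=ScaleThresholds(
            vcdr_975=percentile(clinical_vcdr, 97.5),
            vcdr_995=percentile(clinical_vcdr, 99.5),
            asym_975=percentile(clinical_asym, 97.5),
            asym_995=percentile(clinical_asym, 99.5)),
        iop_995=percentile(iops, 99.5),
        source="derived",
    )


def save_thresholds(thresholds: DiagnosticThresholds, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(thresholds.model_dump(), fh, sort_keys=False)


def load_thresholds(path) -> DiagnosticThresholds:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    data["source"] = "file"
    return DiagnosticThresholds.model_validate(data)
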