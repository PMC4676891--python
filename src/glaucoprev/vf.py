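"""Frequency-doubling technology (FDT) C-20 visual-field interpretation.

The C-20 pattern tests the central 20 degrees at 17 zones (four 2x2 quadrant
blocks plus one central zone).  Screening (C20-1 / C20-5) flags each zone at
one of four probability levels; a threshold test is triggered by sufficiently
deep screening defects.  Grading compares the pattern-deviation probability
(PDP) plot against the total-deviation probability (TDP) plot and assigns one
of: normal, possible, probable or definite glaucomatous field loss, or
"unlikely" when the TDP/PDP relation points to diffuse (e.g. cataract) loss.

The device never publishes zone adjacency or edge membership, so the grid
geometry here is an explicit, configurable constant (:data:`C20_GEOMETRY`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ProbLevel",
    "Zone",
    "VFGeometry",
    "C20_GEOMETRY",
    "DefectMap",
    "VFTestRecord",
    "VFGrade",
    "screening_reliable",
    "threshold_reliable",
    "needs_threshold_test",
    "screening_normal",
    "threshold_normal",
    "grade_defect_map",
    "interpret_vf",
    "reduced_geometry",
]


class ProbLevel(enum.IntEnum):
    """Worst probability level printed for a zone; totally ordered."""

    NONE = 0
    P5 = 1   # p < 5 %
    P2 = 2   # p < 2 %
    P1 = 3   # p < 1 %
    P05 = 4  # p < 0.5 %


#: codes used in delimited files for each level (device print-out style)
LEVEL_CODES = {"0": ProbLevel.NONE, "5": ProbLevel.P5, "2": ProbLevel.P2,
               "1": ProbLevel.P1, "05": ProbLevel.P05}
CODE_FOR_LEVEL = {v: k for k, v in LEVEL_CODES.items()}


@dataclass(frozen=True)
class Zone:
    name: str
    hemifield: str | None  # "superior" | "inferior" | None (central)
    is_edge: bool


@dataclass(frozen=True)
class VFGeometry:
    """Zone layout: hemifield membership, edge set and side-sharing adjacency."""

    zones: tuple[Zone, ...]
    adjacency: Mapping[str, frozenset[str]]

    @property
    def zone_names(self) -> tuple[str, ...]:
        return tuple(z.name for z in self.zones)

    def zone(self, name: str) -> Zone:
        return self._index[name]

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {z.name: z for z in self.zones})

    def hemifield_zones(self, hemi: str) -> tuple[str, ...]:
        return tuple(z.name for z in self.zones if z.hemifield == hemi)


def _grid_geometry(rows: int, cols: int, central: bool,
                   edge_rows: bool = True) -> VFGeometry:
    # rows split evenly into superior (top half) and inferior (bottom half);
    # adjacency = side-sharing, never across the horizontal meridian.
    zones: list[Zone] = []
    half = rows // 2
    for r in range(rows):
        for c in range(cols):
            hemi = "superior" if r < half else "inferior"
            is_edge = c in (0, cols - 1)
            if edge_rows:
                is_edge = is_edge or r in (0, rows - 1)
            zones.append(Zone(f"Z{r}{c}", hemi, is_edge))
    if central:
        zones.append(Zone("C", None, False))
    adj: dict[str, set[str]] = {z.name: set() for z in zones}
    for r in range(rows):
        for c in range(cols):
            me = f"Z{r}{c}"
            hemi_me = "superior" if r < half else "inferior"
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    hemi_other = "superior" if rr < half else "inferior"
                    if hemi_other == hemi_me:
                        adj[me].add(f"Z{rr}{cc}")
    return VFGeometry(tuple(zones), {k: frozenset(v) for k, v in adj.items()})


#: 17-zone C-20 layout: 4x4 grid (2 superior rows, 2 inferior) + central zone.
#: Edge = touching the outer boundary of the pattern (outer ring of the grid).
C20_GEOMETRY = _grid_geometry(4, 4, central=True)


def reduced_geometry() -> VFGeometry:
    """8-zone grid (1 superior row, 1 inferior, 4 columns, no central zone).

    Used for exhaustive enumeration of the grading rules; "edge" is taken as
    the outer columns so the reduced grid still exercises non-edge rules.
    """
    return _grid_geometry(2, 4, central=False, edge_rows=False)


@dataclass
class DefectMap:
    """Per-zone worst probability level for one plot (PDP or TDP)."""

    levels: dict[str, ProbLevel]
    geometry: VFGeometry = field(default_factory=lambda: C20_GEOMETRY)
    plot: str = "PDP"

    def __post_init__(self) -> None:
        names = set(self.geometry.zone_names)
        extra = set(self.levels) - names
        if extra:
            raise ValueError(f"unknown zones in defect map: {sorted(extra)}")
        for name in names:
            self.levels.setdefault(name, ProbLevel.NONE)

    def level(self, zone: str) -> ProbLevel:
        return self.levels[zone]

    def count_at_least(self, level: ProbLevel,
                       zones: Iterable[str] | None = None) -> int:
        names = self.geometry.zone_names if zones is None else zones
        return sum(1 for z in names if self.levels[z] >= level)

    def defect_zones(self, level: ProbLevel = ProbLevel.P5) -> list[str]:
        return [z for z in self.geometry.zone_names if self.levels[z] >= level]

    def severity_score(self) -> int:
        """Sum of level ranks; used to compare TDP against PDP."""
        return sum(int(v) for v in self.levels.values())

    @classmethod
    def empty(cls, geometry: VFGeometry | None = None, plot: str = "PDP") -> "DefectMap":
        return cls({}, geometry or C20_GEOMETRY, plot)


class VFGrade(enum.Enum):
    NORMAL = "normal"
    DEFINITE = "definite"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    UNLIKELY = "unlikely"
    NOT_USABLE = "not_usable"

    @property
    def severity_rank(self) -> int:
        return {"definite": 3, "probable": 2, "possible": 1}.get(self.value, 0)

    @property
    def is_typical_defect(self) -> bool:
        """Does this grade count as glaucoma-typical field loss?"""
        return self in (VFGrade.DEFINITE, VFGrade.PROBABLE, VFGrade.POSSIBLE)


@dataclass
class VFTestRecord:
    mode: str  # "screening" | "threshold"
    fixation_errors: int
    false_positives: int
    pdp_map: DefectMap | None = None
    tdp_map: DefectMap | None = None
    lid_artefact: bool = False
    untestable_reason: str | None = None

    def __post_init__(self) -> None:
        if self.fixation_errors < 0 or self.false_positives < 0:
            raise ValueError("reliability indices must be non-negative")
        if self.mode not in ("screening", "threshold"):
            raise ValueError(f"unknown test mode {self.mode!r}")
        if self.untestable_reason is not None and (
                self.pdp_map is not None or self.tdp_map is not None):
            raise ValueError("untestable test must not carry defect maps")

    @property
    def reliable(self) -> bool:
        if self.mode == "screening":
            return screening_reliable(self.fixation_errors, self.false_positives)
        return threshold_reliable(self.fixation_errors, self.false_positives)

    @property
    def usable(self) -> bool:
        return (self.untestable_reason is None and not self.lid_artefact
                and self.reliable and self.pdp_map is not None
                and self.tdp_map is not None)


def _check_counts(fixation_errors: int, false_positives: int) -> None:
    if fixation_errors < 0 or false_positives < 0:
        raise ValueError("reliability counts must be >= 0")


def screening_reliable(fixation_errors: int, false_positives: int) -> bool:
    """A screening test is reliable with at most one fixation error and at
    most one false positive; failing either index marks the test unreliable."""
    _check_counts(fixation_errors, false_positives)
    return fixation_errors <= 1 and false_positives <= 1


def threshold_reliable(fixation_errors: int, false_positives: int) -> bool:
    """Threshold-mode reliability allows up to two errors on each index."""
    _check_counts(fixation_errors, false_positives)
    return fixation_errors <= 2 and false_positives <= 2


def needs_threshold_test(screening_map: DefectMap) -> bool:
    """Trigger a threshold test on >=3 defects at p<1% or >=2 at p<0.5%.

    Counts are cumulative: a p<0.5% defect also counts at the p<1% level.
    """
    return (screening_map.count_at_least(ProbLevel.P1) >= 3
            or screening_map.count_at_least(ProbLevel.P05) >= 2)


def screening_normal(screening_map: DefectMap) -> bool:
    """A reliable screening map is normal with <=2 defects at p<1% and <=1 at
    p<0.5% (no defect at all is trivially normal).

    This is the exact complement of :func:`needs_threshold_test`, so a map
    triggering a threshold test is never normal.
    """
    return (screening_map.count_at_least(ProbLevel.P1) <= 2
            and screening_map.count_at_least(ProbLevel.P05) <= 1)


def threshold_normal(threshold_map: DefectMap, variant: str = "strict") -> bool:
    """Normality rule for a threshold-mode map.

    Two published phrasings of the rule conflict; both are exposed:

    - ``"strict"`` (default): no defects at p<1% or deeper.
    - ``"lenient"``: <=1 defect at p<2%, or <=2 non-adjacent defects at p<0.5%.
    """
    if variant == "strict":
        return threshold_map.count_at_least(ProbLevel.P1) == 0
    if variant == "lenient":
        if threshold_map.count_at_least(ProbLevel.P2) <= 1:
            return True
        deep = threshold_map.defect_zones(ProbLevel.P05)
        if len(deep) <= 2 and not _any_adjacent_pair(deep, threshold_map.geometry):
            return threshold_map.count_at_least(ProbLevel.P05) == \
                threshold_map.count_at_least(ProbLevel.P5)
        return False
    raise ValueError(f"unknown threshold normality variant {variant!r}")


def _any_adjacent_pair(zones: list[str], geometry: VFGeometry) -> bool:
    zone_set = set(zones)
    for z in zones:
        if geometry.adjacency.get(z, frozenset()) & zone_set:
            return True
    return False


def _table_row_grade(pdp: DefectMap) -> VFGrade:
    """Most severe matching grading row, evaluated on the PDP map alone.

    Count thresholds are minimums and cumulative over levels.  A singleton
    deepest-level defect (p<1% or p<0.5%) at a non-edge location takes the
    hemifield-restricted "probable" row; a singleton p<0.5% defect at an edge
    location, lacking a more specific row, grades definite.
    """
    g = pdp.geometry
    c5 = pdp.count_at_least(ProbLevel.P5)
    c2 = pdp.count_at_least(ProbLevel.P2)
    c1 = pdp.count_at_least(ProbLevel.P1)
    c05 = pdp.count_at_least(ProbLevel.P05)

    # --- definite: any location, any hemifield -------------------------------
    if c5 >= 4 or c2 >= 3 or c1 >= 2:
        return VFGrade.DEFINITE
    if c05 >= 2:
        return VFGrade.DEFINITE
    if c05 == 1:
        (zone,) = pdp.defect_zones(ProbLevel.P05)
        if g.zone(zone).is_edge or g.zone(zone).hemifield is None:
            return VFGrade.DEFINITE

    # --- probable: confined to one hemifield ---------------------------------
    for hemi in ("superior", "inferior"):
        zones = g.hemifield_zones(hemi)
        if pdp.count_at_least(ProbLevel.P5, zones) >= 3:
            return VFGrade.PROBABLE
        if pdp.count_at_least(ProbLevel.P2, zones) >= 2:
            return VFGrade.PROBABLE
    for zone in pdp.defect_zones(ProbLevel.P1):
        z = g.zone(zone)
        if not z.is_edge and z.hemifield is not None:
            return VFGrade.PROBABLE

    # --- possible -------------------------------------------------------------
    if any(g.zone(z).hemifield is not None for z in pdp.defect_zones(ProbLevel.P2)):
        return VFGrade.POSSIBLE
    for hemi in ("superior", "inferior"):
        zones = [z for z in pdp.defect_zones(ProbLevel.P5)
                 if g.zone(z).hemifield == hemi]
        if _any_adjacent_pair(zones, g):
            return VFGrade.POSSIBLE

    return VFGrade.NORMAL


def grade_defect_map(pdp_map: DefectMap, tdp_map: DefectMap,
                     diffuse_fraction: float = 0.5) -> VFGrade:
    """Grade a usable test from its PDP map, checked against the TDP map.

    A defect pattern is unlikely glaucomatous when the TDP plot is *better*
    (strictly lower total severity) than the PDP plot, or when the PDP matches
    no abnormal row while the TDP is diffusely shaded (more than
    ``diffuse_fraction`` of zones flagged) -- the signature of media opacity.
    """
    if set(pdp_map.geometry.zone_names) != set(tdp_map.geometry.zone_names):
        raise ValueError("PDP and TDP maps use different zone sets")
    pdp_score = pdp_map.severity_score()
    tdp_score = tdp_map.severity_score()
    if tdp_score < pdp_score:
        return VFGrade.UNLIKELY
    grade = _table_row_grade(pdp_map)
    if grade is VFGrade.NORMAL and tdp_score > pdp_score:
        n_zones = len(tdp_map.geometry.zone_names)
        if tdp_map.count_at_least(ProbLevel.P5) > diffuse_fraction * n_zones:
            return VFGrade.UNLIKELY
    return grade


def interpret_vf(screening: VFTestRecord | None,
                 threshold: VFTestRecord | None) -> VFGrade:
    """Grade an eye from its FDT tests.

    A usable threshold test takes precedence over screening; with no usable
    test (all unreliable, lid artefact, untestable or absent) the eye's field
    evidence is :attr:`VFGrade.NOT_USABLE`.
    """
    for record in (threshold, screening):
        if record is not None and record.usable:
            return grade_defect_map(record.pdp_map, record.tdp_map)
    return VFGrade.NOT_USABLE
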