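"""Design-based prevalence estimation for a stratified cluster sample.

Clusters are treated as the primary sampling units.  Prevalence is the ratio
estimator (total cases / total examined) with a Taylor-linearised
between-cluster variance, a normal-approximation 95% CI truncated to
[0, 100]%, and the design effect reported as the ratio of the design-based
variance to the simple-random-sampling variance.  Subgroup contrasts use a
Rao-Scott-style corrected chi-square (first-order correction by the mean
cell design effect, with a Satterthwaite-type second-order adjustment of the
degrees of freedom).  Direct age standardisation weights the age-specific
rates by an external standard population and also yields the projected case
burden per age band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceEstimate",
    "AGE_BANDS",
    "age_band",
    "cluster_proportion",
    "crude_prevalence",
    "age_specific_prevalence",
    "subgroup_prevalence",
    "group_difference_test",
    "direct_standardize",
    "blindness_summary",
]

AGE_BANDS = ("40-49", "50-59", "60-69", "70-79", "80+")

SUBGROUP_FACTORS = ("sex", "ethnicity", "literacy", "residence", "visual_status")

#: ethnic groups with fewer members than this are pooled as "Others"
ETHNICITY_MIN_GROUP = 200


def age_band(age_years: int) -> str:
    if age_years < 40:
        raise ValueError(f"age {age_years} below the survey floor of 40")
    if age_years >= 80:
        return "80+"
    lo = (age_years // 10) * 10
    return f"{lo}-{lo + 9}"


@dataclass(frozen=True)
class PrevalenceEstimate:
    numerator: int
    denominator: int
    prevalence: float  # percent
    ci_low: float
    ci_high: float
    design_effect: float
    n_clusters: int

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")

    def as_dict(self) -> dict:
        return {
            "numerator": self.numerator, "denominator": self.denominator,
            "prevalence_pct": round(self.prevalence, 2),
            "ci_low_pct": round(self.ci_low, 2),
            "ci_high_pct": round(self.ci_high, 2),
            "design_effect": round(self.design_effect, 3),
            "n_clusters": self.n_clusters,
        }


def cluster_proportion(cases: np.ndarray, sizes: np.ndarray,
                       z: float = 1.959964) -> PrevalenceEstimate:
    """Ratio-estimated proportion from per-cluster case and size totals.

    Variance is the Taylor linearisation for a ratio of totals with clusters
    as PSUs: v = k/(k-1) * sum_i (y_i - p*n_i)^2 / N^2.
    """
    cases = np.asarray(cases, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    k = len(cases)
    if k < 2:
        raise ValueError("design-based variance needs at least 2 clusters")
    n_total = sizes.sum()
    y_total = cases.sum()
    p = y_total / n_total
    resid = cases - p * sizes
    var = k / (k - 1) * np.sum(resid ** 2) / n_total ** 2
    se = np.sqrt(var)
    srs_var = p * (1 - p) / n_total
    deff = var / srs_var if srs_var > 0 else (0.0 if var == 0 else np.inf)
    return PrevalenceEstimate(
        numerator=int(y_total), denominator=int(n_total),
        prevalence=100 * p,
        ci_low=max(0.0, 100 * (p - z * se)),
        ci_high=min(100.0, 100 * (p + z * se)),
        design_effect=float(deff), n_clusters=k,
    )


def _estimate(df: pd.DataFrame, case_col: str, cluster_col: str,
              ) -> PrevalenceEstimate:
    grouped = df.groupby(cluster_col)[case_col].agg(["sum", "count"])
    return cluster_proportion(grouped["sum"].to_numpy(),
                              grouped["count"].to_numpy())


def crude_prevalence(df: pd.DataFrame, case_col: str = "glaucoma",
                     cluster_col: str = "cluster_id") -> PrevalenceEstimate:
    """Overall prevalence with a cluster-robust 95% CI.

    ``df`` is person-level with one row per examined participant, a boolean
    case column and a cluster identifier.
    """
    return _estimate(df, case_col, cluster_col)


def age_specific_prevalence(df: pd.DataFrame, case_col: str = "glaucoma",
                            cluster_col: str = "cluster_id",
                            age_col: str = "age_years",
                            ) -> dict[str, PrevalenceEstimate]:
    """One estimate per 10-year age band (80+ open-ended); empty bands are
    omitted with a warning."""
    bands = df[age_col].map(age_band)
    out: dict[str, PrevalenceEstimate] = {}
    for band in AGE_BANDS:
        sub = df[bands == band]
        if len(sub) == 0:
            logger.warning("age band %s has no participants; omitted", band)
            continue
        out[band] = _estimate(sub, case_col, cluster_col)
    return out


def _factor_values(df: pd.DataFrame, factor: str) -> pd.Series:
    if factor == "sex":
        return df["sex"]
    if factor == "ethnicity":
        counts = df["ethnicity"].value_counts()
        small = counts[counts < ETHNICITY_MIN_GROUP].index
        return df["ethnicity"].where(~df["ethnicity"].isin(small), "Others")
    if factor == "literacy":
        return df["literate"].map({True: "literate", False: "illiterate"})
    if factor == "residence":
        return df["residence"]
    if factor == "visual_status":
        return df["va_category"].map(
            lambda c: None if pd.isna(c) else
            ("blind" if c == "blind" else "not_blind"))
    raise ValueError(f"unknown subgroup factor {factor!r}; "
                     f"expected one of {SUBGROUP_FACTORS}")


def subgroup_prevalence(df: pd.DataFrame, factor: str,
                        case_col: str = "glaucoma",
                        cluster_col: str = "cluster_id",
                        ) -> dict[str, PrevalenceEstimate]:
    """Per-level prevalence for a socio-demographic factor.

    Rows with a missing factor value are excluded (and counted in the log);
    ethnic groups below :data:`ETHNICITY_MIN_GROUP` members pool as "Others".
    """
    values = _factor_values(df, factor)
    missing = values.isna().sum()
    if missing:
        logger.info("%s: %d missing values excluded", factor, missing)
    kept = df[values.notna()]
    values = values[values.notna()]
    out: dict[str, PrevalenceEstimate] = {}
    for level in sorted(values.unique()):
        out[str(level)] = _estimate(kept[values == level], case_col, cluster_col)
    return out


def group_difference_test(df: pd.DataFrame, factor: str,
                          case_col: str = "glaucoma",
                          cluster_col: str = "cluster_id") -> float:
    """Design-adjusted chi-square p-value for a prevalence difference across
    factor levels (Rao-Scott-style correction).

    The Pearson statistic from the level x outcome table is deflated by the
    mean design effect of the level-specific proportions; a Satterthwaite
    second-order adjustment shrinks the degrees of freedom when the design
    effects are heterogeneous.
    """
    values = _factor_values(df, factor)
    kept = df[values.notna()].copy()
    kept["_level"] = values[values.notna()]
    levels = sorted(kept["_level"].unique())
    if len(levels) < 2:
        raise ValueError("group difference needs at least two factor levels")
    table = pd.crosstab(kept["_level"], kept[case_col].astype(bool))
    if table.shape[1] < 2 or (table.to_numpy().sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)[0]
    deffs = []
    for level in levels:
        sub = kept[kept["_level"] == level]
        try:
            est = _estimate(sub, case_col, cluster_col)
        except ValueError:  # single-cluster level: no design information
            continue
        if np.isfinite(est.design_effect) and est.design_effect > 0:
            deffs.append(est.design_effect)
    d = np.array(deffs) if deffs else np.array([1.0])
    d_bar = max(float(d.mean()), 1e-12)
    cv2 = float(d.var() / d_bar ** 2) if len(d) > 1 else 0.0
    adj = chi2 / (d_bar * (1 + cv2))
    dof = (len(levels) - 1) / (1 + cv2)
    return float(stats.chi2.sf(adj, dof))


def direct_standardize(age_specific_rates: dict[str, float],
                       standard_population: dict[str, float],
                       ) -> tuple[float, dict[str, float], float]:
    """Directly age-standardised rate and projected burden.

    ``age_specific_rates`` are percentages per band; ``standard_population``
    gives the standard population count per band.  Returns (adjusted rate in
    percent, burden per band, total burden); burden_b = rate_b x pop_b.
    Raises when a standard-population band has no observed rate.
    """
    missing = [b for b in standard_population if b not in age_specific_rates]
    if missing:
        raise ValueError(f"no age-specific rate for bands: {missing}")
    total_pop = sum(standard_population.values())
    if total_pop <= 0:
        raise ValueError("standard population must be positive")
    burden = {b: age_specific_rates[b] / 100.0 * pop
              for b, pop in standard_population.items()}
    adjusted = 100.0 * sum(burden.values()) / total_pop
    return adjusted, burden, sum(burden.values())


def blindness_summary(persons: pd.DataFrame, eyes: pd.DataFrame) -> dict:
    """Blindness in relation to glaucoma.

    ``persons``: person-level with boolean ``glaucoma`` and ``va_category``.
    ``eyes``: eye-level with boolean ``glaucoma_eye`` and logMAR
    ``presenting_va``.  Returns the three proportions (percent) with their
    numerators and denominators.
    """
    from .cohort import BLIND_LOGMAR

    gl = persons[persons["glaucoma"].astype(bool)]
    blind = persons["va_category"] == "blind"
    gl_blind = int((gl["va_category"] == "blind").sum())
    gl_eyes = eyes[eyes["glaucoma_eye"].astype(bool)]
    eyes_lt = gl_eyes["presenting_va"].astype(float) > BLIND_LOGMAR
    blind_persons = persons[blind]

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return {
        "persons_blind_pct_among_glaucoma": {
            "numerator": gl_blind, "denominator": len(gl),
            "percent": pct(gl_blind, len(gl))},
        "eyes_va_worse_3_60_pct_among_glaucoma_eyes": {
            "numerator": int(eyes_lt.sum()), "denominator": len(gl_eyes),
            "percent": pct(int(eyes_lt.sum()), len(gl_eyes))},
        "glaucoma_prevalence_among_blind": {
            "numerator": int(blind_persons["glaucoma"].astype(bool).sum()),
            "denominator": len(blind_persons),
            "percent": pct(int(blind_persons["glaucoma"].astype(bool).sum()),
                           len(blind_persons))},
    }
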