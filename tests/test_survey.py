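"""Design-based prevalence estimation, standardisation and subgroup tests."""

import numpy as np
import pandas as pd
import pytest

from glaucoprev.survey import (
    age_band,
    age_specific_prevalence,
    cluster_proportion,
    crude_prevalence,
    direct_standardize,
    group_difference_test,
    subgroup_prevalence,
)


def _df(cases_by_cluster, sizes_by_cluster, **extra_cols):
    rows = []
    for i, (c, n) in enumerate(zip(cases_by_cluster, sizes_by_cluster)):
        for j in range(n):
            rows.append({"cluster_id": f"C{i}", "glaucoma": j < c})
    df = pd.DataFrame(rows)
    for k, v in extra_cols.items():
        df[k] = v
    return df


def _spread(total_cases, total_n, n_clusters=10):
    """Split totals over clusters as evenly as possible."""
    sizes = [total_n // n_clusters] * n_clusters
    for i in range(total_n % n_clusters):
        sizes[i] += 1
    cases = [total_cases // n_clusters] * n_clusters
    for i in range(total_cases % n_clusters):
        cases[i] += 1
    return cases, sizes


class TestCrude:
    def test_survey_totals_reproduced(self):
        # 682 cases among 13 591 examined -> 5.02%
        cases, sizes = _spread(682, 13591)
        est = crude_prevalence(_df(cases, sizes))
        assert round(est.prevalence, 2) == 5.02
        assert est.numerator == 682 and est.denominator == 13591

    def test_all_cases_degenerate(self):
        est = crude_prevalence(_df([5, 5], [5, 5]))
        assert est.prevalence == 100.0
        assert est.ci_low == est.ci_high == 100.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            crude_prevalence(_df([2], [10]))

    def test_ci_coverage_near_nominal(self, rng):
        """Cluster-robust CI covers a common true proportion ~95% of the
        time (1000 replicates, 200 clusters of 20, p = 0.05)."""
        covered = 0
        reps = 1000
        for _ in range(reps):
            cases = rng.binomial(20, 0.05, size=200)
            est = cluster_proportion(cases, np.full(200, 20))
            covered += est.ci_low <= 5.0 <= est.ci_high
        assert 0.92 <= covered / reps <= 0.975

    def test_design_effect_near_one_for_random_clusters(self, rng):
        """With cluster labels independent of outcome the design effect is
        approximately 1."""
        deffs = []
        for _ in range(50):
            outcomes = rng.random(2000) < 0.05
            clusters = rng.integers(0, 100, size=2000)
            df = pd.DataFrame({"cluster_id": clusters, "glaucoma": outcomes})
            deffs.append(crude_prevalence(df).design_effect)
        assert 0.85 <= np.mean(deffs) <= 1.15

    def test_ci_width_shrinks_with_cluster_count(self, rng):
        def width(k):
            ws = []
            for _ in range(30):
                cases = rng.binomial(45, 0.05, size=k)
                est = cluster_proportion(cases, np.full(k, 45))
                ws.append(est.ci_high - est.ci_low)
            return np.mean(ws)

        ratio = width(400) / width(100)
        assert 0.35 <= ratio <= 0.65  # ~1/2 for 4x the clusters


class TestAgeSpecific:
    @pytest.mark.parametrize("band_cases,band_n,expected", [
        (93, 4889, 1.90), (130, 3577, 3.63), (178, 2773, 6.42),
        (178, 1653, 10.77), (103, 699, 14.74),
    ])
    def test_survey_band_rates(self, band_cases, band_n, expected):
        cases, sizes = _spread(band_cases, band_n)
        est = crude_prevalence(_df(cases, sizes))
        assert round(est.prevalence, 2) == expected

    def test_bands_partition_the_cohort(self):
        ages = np.concatenate([np.full(30, a) for a in
                               (40, 49, 50, 65, 79, 80, 91)])
        cases, sizes = _spread(21, len(ages))
        df = _df(cases, sizes)
        df["age_years"] = ages
        table = age_specific_prevalence(df)
        assert sum(e.numerator for e in table.values()) == 21
        assert sum(e.denominator for e in table.values()) == len(ages)

    def test_single_band_equals_crude(self):
        cases, sizes = _spread(10, 200)
        df = _df(cases, sizes, age_years=45)
        table = age_specific_prevalence(df)
        assert list(table) == ["40-49"]
        assert table["40-49"].prevalence == crude_prevalence(df).prevalence

    def test_age_band_boundaries(self):
        assert [age_band(a) for a in (40, 49, 50, 79, 80, 95)] == \
            ["40-49", "40-49", "50-59", "70-79", "80+", "80+"]
        with pytest.raises(ValueError):
            age_band(39)


class TestSubgroups:
    def test_survey_subgroup_rates(self):
        # Igbo 149/1918 -> 7.77%; blind 136/569 -> 23.90%
        cases, sizes = _spread(149, 1918)
        assert round(crude_prevalence(_df(cases, sizes)).prevalence, 2) == 7.77
        cases, sizes = _spread(136, 569)
        assert round(crude_prevalence(_df(cases, sizes)).prevalence, 2) == 23.90

    def test_small_ethnic_groups_pooled(self):
        cases, sizes = _spread(30, 600)
        df = _df(cases, sizes)
        df["ethnicity"] = ["Hausa"] * 400 + ["Tiny1"] * 100 + ["Tiny2"] * 100
        table = subgroup_prevalence(df, "ethnicity")
        assert set(table) == {"Hausa", "Others"}
        assert table["Others"].denominator == 200

    def test_single_level_equals_crude(self):
        cases, sizes = _spread(12, 300)
        df = _df(cases, sizes, sex="female")
        table = subgroup_prevalence(df, "sex")
        assert list(table) == ["female"]
        assert table["female"].prevalence == crude_prevalence(df).prevalence

    def test_unknown_factor_rejected(self):
        df = _df([1, 1], [10, 10])
        with pytest.raises(ValueError, match="unknown subgroup factor"):
            subgroup_prevalence(df, "favourite_colour")


class TestGroupDifference:
    def test_identical_proportions_give_p_one(self):
        # every cluster contributes the same 1-in-20 proportion in each arm
        rows = []
        for i in range(40):
            for sex in ("male", "female"):
                for j in range(20):
                    rows.append({"cluster_id": f"C{i}", "sex": sex,
                                 "glaucoma": j == 0})
        p = group_difference_test(pd.DataFrame(rows), "sex")
        assert p > 0.99

    def test_power_for_strong_effect(self, rng):
        """p1=0.02 vs p2=0.10 over 100 clusters is detected at p<0.001 in
        nearly all replicates."""
        hits = 0
        reps = 60
        for _ in range(reps):
            rows = []
            for i in range(100):
                for sex, p in (("male", 0.02), ("female", 0.10)):
                    k = rng.binomial(25, p)
                    for j in range(25):
                        rows.append({"cluster_id": f"C{i}", "sex": sex,
                                     "glaucoma": j < k})
            if group_difference_test(pd.DataFrame(rows), "sex") < 0.001:
                hits += 1
        assert hits >= int(0.95 * reps)

    def test_single_level_rejected(self):
        df = _df([1, 1], [10, 10], sex="female")
        with pytest.raises(ValueError, match="two factor levels"):
            group_difference_test(df, "sex")


class TestStandardization:
    def test_identity_weights_reproduce_crude(self):
        rates = {"40-49": 2.0, "50-59": 4.0, "60-69": 8.0}
        pops = {"40-49": 500, "50-59": 300, "60-69": 200}
        crude = (2.0 * 500 + 4.0 * 300 + 8.0 * 200) / 1000
        adjusted, _, _ = direct_standardize(rates, pops)
        assert adjusted == pytest.approx(crude)

    def test_hand_arithmetic_oracle(self):
        adjusted, burden, total = direct_standardize(
            {"a": 10.0, "b": 20.0}, {"a": 100, "b": 300})
        assert adjusted == pytest.approx(17.5)
        assert burden == {"a": 10.0, "b": 60.0}
        assert total == pytest.approx(70.0)

    def test_zero_rates(self):
        adjusted, _, total = direct_standardize(
            {"a": 0.0, "b": 0.0}, {"a": 10, "b": 10})
        assert adjusted == 0.0 and total == 0.0

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError, match="80"):
            direct_standardize({"40-49": 2.0}, {"40-49": 10, "80+": 5})
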