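"""Statistics battery: oracle equivalences and calibration."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from epiphen.stats import (ContingencyTable2x2, anova2_tukey, compare_two,
                           fisher_exact, kruskal_dunn, pearson_r2,
                           proportion_pct, rout_outliers)


def fisher_two_sided_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Integer-numerator arithmetic over the common denominator C(n, c1)
    makes the "probability at most that of the observed table" comparison
    exact (independent of scipy)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    numerators = {x: comb(r1, x) * comb(n - r1, c1 - x)
                  for x in range(lo, hi + 1)}
    num_obs = numerators[a]
    total = sum(num for num in numerators.values() if num <= num_obs)
    return Fraction(total, comb(n, c1))


class TestFisher:
    def test_strong_sex_difference_table(self):
        # 108/154 female vs 17/120 male seizures with postictal depression
        assert fisher_exact([[108, 46], [17, 103]]) < 0.0001

    def test_symmetric_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_first_seizure_severity_table(self):
        p = fisher_exact([[2, 9], [4, 10]])
        assert p == pytest.approx(
            float(fisher_two_sided_enumeration(2, 9, 4, 10)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 16, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = fisher_exact([[a, b], [c, d]])
            oracle = float(fisher_two_sided_enumeration(a, b, c, d))
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        assert 0 < fisher_exact(ContingencyTable2x2(3, 4, 5, 6)) <= 1


class TestCompareTwo:
    def test_identical_groups(self):
        out = compare_two([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="student")
        assert out["statistic"] == 0.0 and out["p"] == 1.0

    def test_separated_groups_closed_form(self):
        # means 2 vs 102, s^2 = 1 each: t = -100 / sqrt(2/3), df = 4
        out = compare_two([1, 2, 3], [101, 102, 103], mode="student")
        assert out["statistic"] == pytest.approx(-100 / np.sqrt(2 / 3))
        assert out["p"] < 0.001

    def test_auto_selects_welch_for_unequal_variance(self):
        rng = np.random.default_rng(4)
        out = compare_two(rng.normal(0, 1, 12), rng.normal(0, 10, 12))
        assert out["mode"] == "welch"

    def test_auto_selects_student_for_homoscedastic_normal(self):
        rng = np.random.default_rng(5)
        out = compare_two(rng.normal(0, 1, 12), rng.normal(0.5, 1, 12))
        assert out["mode"] == "student"

    def test_auto_selects_mannwhitney_for_skewed(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([np.zeros(8), rng.exponential(5, 8) ** 2])
        y = rng.normal(5, 1, 12)
        assert compare_two(x, y)["mode"] == "mannwhitney"

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        p1 = compare_two(x, y, mode="welch")["p"]
        p2 = compare_two(x[::-1], y[::-1], mode="welch")["p"]
        assert p1 == p2


def balanced_anova_oracle(df):
    """Textbook sums-of-squares decomposition for a balanced 2x2 design."""
    grand = df["value"].mean()
    n_cell = df.groupby(["genotype", "sex"]).size().iloc[0]
    a_means = df.groupby("genotype")["value"].mean()
    b_means = df.groupby("sex")["value"].mean()
    cell_means = df.groupby(["genotype", "sex"])["value"].mean()
    n_a = df["sex"].nunique() * n_cell
    n_b = df["genotype"].nunique() * n_cell
    ss_a = (n_a * (a_means - grand) ** 2).sum()
    ss_b = (n_b * (b_means - grand) ** 2).sum()
    ss_cells = (n_cell * (cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    resid = df["value"] - df.set_index(["genotype", "sex"]).index.map(
        cell_means)
    ss_e = (resid ** 2).sum()
    df_e = len(df) - 4
    ms = [ss_a, ss_b, ss_ab]
    f = [m / 1 / (ss_e / df_e) for m in ms]
    return f


class TestAnova:
    def _balanced(self):
        rng = np.random.default_rng(8)
        rows = []
        means = {("Cre-", "F"): 10, ("Cre-", "M"): 12,
                 ("Cre+", "F"): 9, ("Cre+", "M"): 13}
        for (g, s), mu in means.items():
            for v in rng.normal(mu, 2, 8):
                rows.append({"value": v, "genotype": g, "sex": s})
        return pd.DataFrame(rows)

    def test_matches_sums_of_squares_oracle(self):
        df = self._balanced()
        res = anova2_tukey(df)
        f_a, f_b, f_ab = balanced_anova_oracle(df)
        assert res["genotype"][0] == pytest.approx(f_a, abs=1e-8)
        assert res["sex"][0] == pytest.approx(f_b, abs=1e-8)
        assert res["interaction"][0] == pytest.approx(f_ab, abs=1e-8)

    def test_tukey_matches_statsmodels_on_balanced_cells(self):
        """Tukey-Kramer p over the 4 cells equals statsmodels'
        pairwise_tukeyhsd when the MSE is the same (balanced one-way
        equivalence)."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = self._balanced()
        res = anova2_tukey(df)
        labels = df["genotype"] + "/" + df["sex"]
        hsd = pairwise_tukeyhsd(df["value"].to_numpy(), labels.to_numpy())
        sm_p = {tuple(sorted((r[0], r[1]))): r[3]
                for r in hsd.summary().data[1:]}
        for (a, b), p in res["tukey"].items():
            assert p == pytest.approx(sm_p[tuple(sorted((a, b)))], abs=2e-4)

    def test_interaction_only_pattern(self):
        rng = np.random.default_rng(9)
        rows = []
        for g, s, delta in [("Cre-", "F", 5), ("Cre-", "M", -5),
                            ("Cre+", "F", -5), ("Cre+", "M", 5)]:
            for v in rng.normal(delta, 1, 10):
                rows.append({"value": v, "genotype": g, "sex": s})
        res = anova2_tukey(pd.DataFrame(rows))
        assert res["interaction"][1] < 0.01
        assert res["genotype"][1] > 0.1 and res["sex"][1] > 0.1

    def test_degenerate_zero_variance(self):
        rows = [{"value": 5.0, "genotype": g, "sex": s}
                for g in ("a", "b") for s in ("F", "M") for _ in range(3)]
        res = anova2_tukey(pd.DataFrame(rows))
        assert res["degenerate"]
        assert np.isnan(res["genotype"][0])

    def test_unbalanced_cells_allowed(self):
        rng = np.random.default_rng(10)
        rows = []
        for (g, s), n in {("a", "F"): 3, ("a", "M"): 7,
                          ("b", "F"): 5, ("b", "M"): 4}.items():
            for v in rng.normal(0, 1, n):
                rows.append({"value": v, "genotype": g, "sex": s})
        res = anova2_tukey(pd.DataFrame(rows))
        assert 0 <= res["genotype"][1] <= 1


class TestKruskalDunn:
    def test_identical_groups(self):
        out = kruskal_dunn({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert out["p"] > 0.99

    def test_fully_separated_groups(self):
        out = kruskal_dunn({"a": list(range(10)),
                            "b": list(range(100, 110)),
                            "c": list(range(200, 210))})
        assert out["p"] < 0.001
        assert out["dunn"][("a", "c")] < 0.01

    def test_tie_corrected_h_hand_computation(self):
        # 6 observations with one tied pair across groups
        groups = {"a": [1.0, 2.0, 2.0], "b": [3.0, 4.0, 5.0]}
        pooled = np.array([1, 2, 2, 3, 4, 5], dtype=float)
        ranks = {1.0: 1, 2.0: 2.5, 3.0: 4, 4.0: 5, 5.0: 6}
        r_a = ranks[1.0] + ranks[2.0] * 2
        r_b = ranks[3.0] + ranks[4.0] + ranks[5.0]
        n = 6
        h = 12 / (n * (n + 1)) * (r_a ** 2 / 3 + r_b ** 2 / 3) - 3 * (n + 1)
        tie = 1 - (2 ** 3 - 2) / (n ** 3 - n)
        out = kruskal_dunn(groups)
        assert out["H"] == pytest.approx(h / tie)

    def test_permutation_oracle_for_moderate_separation(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1.5, 1, 8)
        out = kruskal_dunn({"a": a, "b": b})
        # permutation distribution of H under label exchange
        pooled = np.concatenate([a, b])
        count = 0
        reps = 2000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            h = kruskal_dunn({"a": perm[:8], "b": perm[8:]})["H"]
            count += h >= out["H"] - 1e-12
        p_perm = count / reps
        assert out["p"] == pytest.approx(p_perm, abs=0.05)


class TestRout:
    def test_gross_outlier_flagged(self):
        sample = list(np.arange(0.1, 1.05, 0.1)) + [100.0]
        out = rout_outliers(sample)
        assert out["outliers"].tolist() == [100.0]

    def test_identical_triplet_unflagged(self):
        out = rout_outliers([5.0, 5.0, 5.0])
        assert out["outliers"].size == 0

    def test_clean_gaussian_false_flag_rate(self):
        rng = np.random.default_rng(12)
        flagged = total = 0
        for _ in range(1000):
            out = rout_outliers(rng.standard_normal(20))
            flagged += out["outliers"].size
            total += 20
        assert flagged / total <= 0.02

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0])

    def test_partition(self):
        x = np.array([0.0, 0.1, 0.2, 50.0])
        out = rout_outliers(x)
        assert sorted(out["kept"].tolist() + out["outliers"].tolist()) \
            == sorted(x.tolist())


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        out = pearson_r2(x, 2 * x)
        assert out["r2"] == pytest.approx(1.0)

    def test_orthogonal(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_r2(x, y)["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert pearson_r2(x, y)["r"] == pytest.approx(r_hand)

    def test_validation(self):
        with pytest.raises(ValueError):
            pearson_r2([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_r2([1, 2, np.nan], [3, 4, 5])


class TestProportion:
    @pytest.mark.parametrize("num,den,expect", [
        (17, 120, 14.2), (2, 11, 18.2), (4, 14, 28.6), (0, 10, 0.0),
    ])
    def test_printed_percentages(self, num, den, expect):
        assert proportion_pct(num, den) == expect

    def test_half_up_rounding(self):
        assert proportion_pct(1, 8, decimals=0) == 13.0   # 12.5 rounds up

    def test_validation(self):
        with pytest.raises(ValueError):
            proportion_pct(5, 4)
        with pytest.raises(ValueError):
            proportion_pct(1, 0)
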