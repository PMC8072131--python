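"""Group-comparison battery: rank-sum, KS, two-way ANOVA, post hoc."""

import itertools

import numpy as np
import pandas as pd
import pytest

import nichequant as nq
from nichequant.exceptions import RankDeficiencyError


def exhaustive_rank_sum_p(a, b):
    """Independent oracle: enumerate all assignments of pooled midranks."""
    import scipy.stats as sps

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    ws = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), na)]
    ws = np.asarray(ws)
    le = np.mean(ws <= w_obs + 1e-9)
    ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(le, ge))


class TestRankSum:
    def test_separated_samples_match_enumeration(self):
        a, b = [1, 2, 3], [4, 5, 6]
        res = nq.rank_sum_test(a, b)
        assert res.statistic == 6.0
        assert res.pvalue == pytest.approx(2 / 20)  # C(6,3)=20 assignments
        assert res.pvalue == pytest.approx(exhaustive_rank_sum_p(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, rng.integers(3, 7)).astype(float)  # ties likely
        b = rng.integers(0, 6, rng.integers(3, 7)).astype(float)
        assert nq.rank_sum_test(a, b).pvalue == pytest.approx(exhaustive_rank_sum_p(a, b))

    def test_identical_samples_give_p_one(self):
        res = nq.rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.pvalue == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=15)
        assert nq.rank_sum_test(a, b).pvalue == pytest.approx(
            nq.rank_sum_test(b, a).pvalue, abs=1e-12
        )

    def test_large_sample_normal_approximation_reasonable(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        b = rng.normal(loc=2.0, size=40)
        res = nq.rank_sum_test(a, b)
        assert res.extra["method"] == "normal"
        assert res.pvalue < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            nq.rank_sum_test([], [1.0])


class TestKolmogorovSmirnov:
    def test_identical_samples_have_zero_distance(self):
        x = np.arange(10.0)
        assert nq.ks_two_sample(x, x).statistic == 0.0

    def test_disjoint_supports_have_distance_one(self):
        res = nq.ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic == 1.0

    def test_statistic_matches_brute_force_ecdf_gap(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=30)
        res = nq.ks_two_sample(a, b)
        # independent oracle: max ECDF gap over all observed points
        pts = np.concatenate([a, b])
        gap = max(
            abs(np.mean(a <= t) - np.mean(b <= t)) for t in pts
        )
        assert res.statistic == pytest.approx(gap, abs=1e-12)


class TestTwoWayAnova:
    @staticmethod
    def _closed_form_balanced(df, value):
        """Textbook sums-of-squares oracle for a balanced two-way layout."""
        grand = df[value].mean()
        n = len(df)
        ss_a = sum(
            len(sub) * (sub[value].mean() - grand) ** 2 for _, sub in df.groupby("age_group")
        )
        ss_b = sum(len(sub) * (sub[value].mean() - grand) ** 2 for _, sub in df.groupby("sex"))
        ss_cells = sum(
            len(sub) * (sub[value].mean() - grand) ** 2
            for _, sub in df.groupby(["age_group", "sex"])
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_tot = ((df[value] - grand) ** 2).sum()
        ss_err = ss_tot - ss_cells
        a = df["age_group"].nunique()
        b = df["sex"].nunique()
        df_err = n - a * b
        return {
            "age_group": (ss_a / (a - 1)) / (ss_err / df_err),
            "sex": (ss_b / (b - 1)) / (ss_err / df_err),
            "age_group:sex": (ss_ab / ((a - 1) * (b - 1))) / (ss_err / df_err),
        }

    def _balanced_table(self, seed=0, reps=4):
        rng = np.random.default_rng(seed)
        rows = []
        for age in ("2mo", "18mo", "22mo"):
            for sex in ("female", "male"):
                for _ in range(reps):
                    rows.append({"age_group": age, "sex": sex, "v": rng.normal()})
        return pd.DataFrame(rows)

    def test_balanced_2x3_matches_closed_form_to_1e8(self):
        df = self._balanced_table()
        oracle = self._closed_form_balanced(df, "v")
        for res in nq.two_way_anova(df, "v"):
            assert res.statistic == pytest.approx(oracle[res.comparison], abs=1e-8)

    def test_identical_values_give_zero_f(self):
        df = self._balanced_table()
        df["v"] = 3.14
        for res in nq.two_way_anova(df, "v"):
            assert res.statistic == 0.0
            assert res.pvalue == 1.0

    def test_additive_effects_without_noise(self):
        rows = []
        age_eff = {"2mo": 0.0, "22mo": 2.0}
        sex_eff = {"female": 0.0, "male": 5.0}
        for age in age_eff:
            for sex in sex_eff:
                for _ in range(3):
                    rows.append(
                        {"age_group": age, "sex": sex, "v": 1.0 + age_eff[age] + sex_eff[sex]}
                    )
        results = {r.comparison: r for r in nq.two_way_anova(pd.DataFrame(rows), "v")}
        assert results["age_group:sex"].statistic == 0.0
        assert results["age_group"].pvalue == 0.0  # infinite F guarded as p -> 0
        assert results["sex"].pvalue == 0.0

    def test_empty_cell_raises_naming_the_cell(self):
        df = self._balanced_table()
        df = df[~((df.age_group == "18mo") & (df.sex == "male"))]
        with pytest.raises(RankDeficiencyError, match="18mo"):
            nq.two_way_anova(df, "v")

    def test_balanced_design_order_invariance(self):
        df = self._balanced_table(seed=9)
        f1 = {r.comparison: r.statistic for r in nq.two_way_anova(df, "v")}
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f2 = {r.comparison: r.statistic for r in nq.two_way_anova(shuffled, "v")}
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-10)


class TestPosthoc:
    def test_single_comparison_unchanged(self):
        assert nq.sidak_adjust([0.04], m=1)[0] == pytest.approx(0.04)

    def test_sidak_formula(self):
        assert nq.sidak_adjust([0.05], m=3)[0] == pytest.approx(0.142625)

    def test_adjusted_p_monotone_and_conservative(self):
        p = np.linspace(0.0, 1.0, 21)
        adj = nq.sidak_adjust(p, m=4)
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_tukey_all_pairs(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(loc=i, size=8) for i, k in enumerate("abc")}
        res = nq.tukey_hsd(groups)
        assert len(res) == 3
        assert all(0 <= r.pvalue <= 1 for r in res)

    def test_posthoc_adjust_dispatch(self):
        assert nq.posthoc_adjust([0.05], method="sidak", m=3)[0] == pytest.approx(0.142625)
        with pytest.raises(ValueError):
            nq.posthoc_adjust([0.05], method="tukey")


class TestGroupReport:
    def test_report_structure(self):
        rng = np.random.default_rng(11)
        rows = []
        for sid in range(8):
            age = "2mo" if sid % 2 else "22mo"
            sex = "male" if sid % 4 < 2 else "female"
            for _ in range(20):
                rows.append(
                    {"sample_id": f"s{sid}", "age_group": age, "sex": sex, "v": rng.normal()}
                )
        report = nq.group_report(pd.DataFrame(rows), "v", summary="median")
        assert report["metric"] == "v"
        assert "object_level_rank_sum" in report
        assert "per_sample_anova" in report
        for r in report["object_level_rank_sum"]:
            assert r["pvalue_sidak"] >= r["pvalue"] - 1e-12
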