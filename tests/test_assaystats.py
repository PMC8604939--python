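import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sstrkit.assaystats import (
    OutlierRule,
    PlateCountRecord,
    basic_tests,
    compare_to_control,
    dunnett_critical_value,
    editing_efficiency,
    flag_outliers,
    groups_from_frame,
    pairwise_unequal_var,
    summarize_groups,
)


class TestEditingEfficiency:
    def test_equal_volumes_simple_percentage(self):
        rec = PlateCountRecord("r1", "wt", 100, 450.0, 5, 450.0)
        assert editing_efficiency(rec) == pytest.approx(5.0)

    def test_volume_normalization(self):
        # 10 colonies from 4000 uL selective vs 200 from 50 uL non-selective
        rec = PlateCountRecord("r1", "wt", 200, 50.0, 10, 4000.0)
        assert editing_efficiency(rec) == pytest.approx(0.0625)

    def test_zero_nonselective_reported_missing(self):
        rec = PlateCountRecord("r1", "wt", 0, 50.0, 3, 4000.0)
        assert np.isnan(editing_efficiency(rec))

    def test_common_factor_invariance(self, rng):
        for _ in range(20):
            c_ns, c_s = rng.integers(1, 500), rng.integers(0, 50)
            v_ns, v_s = rng.uniform(10, 500), rng.uniform(10, 5000)
            f = rng.uniform(0.5, 4.0)
            base = editing_efficiency(
                PlateCountRecord("r", "g", c_ns, v_ns, c_s, v_s)
            )
            scaled = editing_efficiency(
                PlateCountRecord(
                    "r", "g", int(c_ns * 3), v_ns * 3 * f, int(c_s * 3), v_s * 3 * f
                )
            )
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_vectorized_matches_scalar(self):
        df = pd.DataFrame(
            {
                "colonies_nonselective": [100, 0, 200],
                "volume_nonselective": [450.0, 50.0, 50.0],
                "colonies_selective": [5, 3, 10],
                "volume_selective": [450.0, 4000.0, 4000.0],
            }
        )
        out = editing_efficiency(df)
        assert out.iloc[0] == pytest.approx(5.0)
        assert np.isnan(out.iloc[1])
        assert out.iloc[2] == pytest.approx(0.0625)

    def test_can_exceed_100_percent(self):
        rec = PlateCountRecord("r", "g", 10, 450.0, 20, 450.0)
        assert editing_efficiency(rec) == pytest.approx(200.0)


class TestFlagOutliers:
    def test_below_min_n_never_flags(self):
        assert not flag_outliers([1.0, 2.0, 3.0, 1e9]).any()

    def test_manual_quartile_example(self):
        # inclusive quartiles: Q1=2, Q3=3, IQR=1, fences [0.5, 4.5]
        flags = flag_outliers([1, 2, 2, 3, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_matches_brute_force_fences(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 13))
            vals = rng.normal(0, 1, n) * rng.uniform(0.5, 20)
            if rng.random() < 0.5:
                vals[0] *= 10
            sv = np.sort(vals)
            q1 = np.interp(0.25 * (n - 1), np.arange(n), sv)
            q3 = np.interp(0.75 * (n - 1), np.arange(n), sv)
            iqr = q3 - q1
            expected = (vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)
            assert flag_outliers(vals).tolist() == expected.tolist()

    def test_nonfinite_values_ignored(self):
        vals = [1.0, 2.0, 2.0, 3.0, 100.0, np.nan]
        flags = flag_outliers(vals)
        assert flags.tolist() == [False, False, False, False, True, False]

    def test_summary_retains_outliers_in_mean(self):
        df = pd.DataFrame(
            {"genotype": ["g"] * 5, "efficiency_pct": [1, 2, 2, 3, 100.0]}
        )
        summary = summarize_groups(df)
        assert summary.loc[0, "n_outliers"] == 1
        assert summary.loc[0, "mean"] == pytest.approx(np.mean([1, 2, 2, 3, 100]))
        assert summary.loc[0, "n"] == 5


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 5)
        table = compare_to_control({"ctrl": a, "trt": b}, "ctrl")
        t, p = stats.ttest_ind(b, a, equal_var=True)
        assert table.loc[0, "statistic"] == pytest.approx(t)
        assert table.loc[0, "p_adj"] == pytest.approx(p)

    def test_matches_reference_implementation(self, rng):
        groups = {
            "ctrl": rng.normal(0, 1, 7),
            "a": rng.normal(0.5, 1, 5),
            "b": rng.normal(1.0, 2, 6),
            "c": rng.normal(0.0, 1, 6),
        }
        mine = compare_to_control(groups, "ctrl")
        ref = stats.dunnett(
            *(groups[g] for g in ("a", "b", "c")), control=groups["ctrl"]
        )
        assert np.allclose(mine["statistic"], ref.statistic, atol=1e-10)
        assert np.allclose(mine["p_adj"], ref.pvalue, atol=2e-3)

    def test_adjusted_p_not_below_raw_p(self, rng):
        for _ in range(20):
            groups = {
                "ctrl": rng.normal(0, 1, 5),
                **{
                    f"t{i}": rng.normal(rng.normal(0, 0.5), 1, 5)
                    for i in range(3)
                },
            }
            table = compare_to_control(groups, "ctrl")
            df = table["df"].iloc[0]
            raw = 2 * stats.t.sf(np.abs(table["statistic"]), df)
            assert (table["p_adj"].to_numpy() >= raw - 1e-9).all()

    def test_missing_control_label_errors(self, rng):
        with pytest.raises(ValueError, match="control"):
            compare_to_control({"a": rng.normal(0, 1, 4)}, "ctrl")

    def test_family_error_rate_calibrated(self, rng):
        """Under the global null the probability that any comparison exceeds
        the two-sided critical value is the nominal alpha."""
        n0, ns = 6, [6, 6, 6]
        crit = dunnett_critical_value(n0, ns, alpha=0.05)
        k = len(ns)
        reps = 10_000
        df = n0 + sum(ns) - (k + 1)
        rejections = 0
        for _ in range(reps):
            control = rng.normal(0, 1, n0)
            trts = [rng.normal(0, 1, n) for n in ns]
            allv = [control, *trts]
            s2 = sum((len(v) - 1) * np.var(v, ddof=1) for v in allv) / df
            tmax = max(
                abs(np.mean(t) - np.mean(control))
                / np.sqrt(s2 * (1 / len(t) + 1 / n0))
                for t in trts
            )
            rejections += tmax > crit
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


class TestGamesHowell:
    def test_identical_groups_give_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        table = pairwise_unequal_var({"a": g, "b": g.copy()})
        assert table.loc[0, "p_adj"] == pytest.approx(1.0)
        assert table.loc[0, "statistic"] == 0.0

    def test_formula_by_hand_three_groups(self, rng):
        groups = {
            "a": rng.normal(0, 1, 5),
            "b": rng.normal(1, 3, 7),
            "c": rng.normal(0.5, 0.2, 4),
        }
        table = pairwise_unequal_var(groups).set_index(["group_a", "group_b"])
        k = 3
        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            va, na = np.var(groups[a], ddof=1), len(groups[a])
            vb, nb = np.var(groups[b], ddof=1), len(groups[b])
            se2 = va / na + vb / nb
            t = (np.mean(groups[a]) - np.mean(groups[b])) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df)
            row = table.loc[(a, b)]
            assert row["statistic"] == pytest.approx(t)
            assert row["df"] == pytest.approx(df)
            assert row["p_adj"] == pytest.approx(p)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = {
            "wt": rng.normal(3, 0.5, 5),
            "ku": rng.normal(20, 6, 4),
            "polq": np.abs(rng.normal(0.05, 0.05, 4)),
        }
        df = pd.DataFrame(
            [(g, v) for g, vals in groups.items() for v in vals],
            columns=["genotype", "eff"],
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="eff", between="genotype")
        mine = pairwise_unequal_var(groups)
        ref = ref.sort_values(["A", "B"]).reset_index(drop=True)
        mine = (
            mine.assign(
                A=np.minimum(mine["group_a"], mine["group_b"]),
                B=np.maximum(mine["group_a"], mine["group_b"]),
            )
            .sort_values(["A", "B"])
            .reset_index(drop=True)
        )
        assert np.allclose(np.abs(mine["statistic"]), np.abs(ref["T"]), atol=1e-9)
        assert np.allclose(mine["df"], ref["df"], atol=1e-9)
        assert np.allclose(mine["p_adj"], ref["pval"], atol=1e-9)

    @pytest.mark.parametrize("n,tol", [(50, 2e-3), (200, 5e-4)])
    def test_converges_to_tukey_under_equal_variance(self, rng, n, tol):
        """With identical sample variances and equal n the Welch machinery
        converges to Tukey's HSD as n grows (residual gap comes from the
        pairwise vs pooled degrees of freedom)."""
        base = rng.normal(0, 1, n)
        groups = {"a": base, "b": base + 0.2, "c": base + 0.45}
        gh = pairwise_unequal_var(groups)
        tk = stats.tukey_hsd(*groups.values())
        pairs = [(0, 1), (0, 2), (1, 2)]
        for row, (i, j) in zip(gh.itertuples(), pairs):
            assert row.p_adj == pytest.approx(tk.pvalue[i, j], abs=tol)

    def test_control_only_filtering(self, rng):
        groups = {g: rng.normal(0, 1, 5) for g in ("wt", "a", "b", "c")}
        table = pairwise_unequal_var(groups, control_label="wt")
        assert len(table) == 3
        assert (
            (table["group_a"] == "wt") | (table["group_b"] == "wt")
        ).all()

    def test_small_group_excluded_with_warning(self, rng):
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 5),
                  "c": np.array([1.0])}
        with pytest.warns(UserWarning, match="excluding"):
            table = pairwise_unequal_var(groups)
        assert len(table) == 1


class TestBasicTests:
    def test_one_sample_t_at_null_mean(self):
        res = basic_tests([5.0, 5.0 + 1e-12, 5.0 - 1e-12, 5.0], "t_one_sample",
                          popmean=5.0, alternative="less")
        assert res.statistic == pytest.approx(0.0, abs=1e-3)
        assert res.p == pytest.approx(0.5, abs=1e-3)

    def test_shapiro_matches_frozen_reference(self):
        # reference computed independently with R's shapiro.test
        x = [2.1, 3.4, 1.9, 5.6, 4.4, 3.3, 2.8, 4.9, 3.7, 2.2]
        res = basic_tests(x, "shapiro")
        assert res.statistic == pytest.approx(0.9465216882, abs=1e-6)
        assert res.p == pytest.approx(0.6275681670, abs=1e-4)

    def test_shapiro_rejects_constant_data(self):
        with pytest.raises(ValueError, match="constant"):
            basic_tests([1.0, 1.0, 1.0, 1.0], "shapiro")

    def test_levene_mean_centring_default(self, rng):
        groups = [rng.normal(0, s, 8) for s in (1, 1, 5)]
        res = basic_tests(groups, "levene")
        W, p = stats.levene(*groups, center="mean")
        assert res.statistic == pytest.approx(W)
        assert res.p == pytest.approx(p)
        assert "mean" in res.method

    def test_anova_identical_groups_zero_f(self):
        res = basic_tests([[1.0, 2, 3]] * 4, "anova")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_one_sided_two_sample_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        res = basic_tests([a, b], "t_two_sample", alternative="less")
        t, p = stats.ttest_ind(a, b, alternative="less")
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.df == len(a) + len(b) - 2

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            basic_tests([1, 2], "bogus")


class TestGroupsFromFrame:
    def test_missing_replicates_dropped(self):
        df = pd.DataFrame(
            {"genotype": ["a", "a", "b"], "efficiency_pct": [1.0, np.nan, 2.0]}
        )
        groups = groups_from_frame(df)
        assert groups["a"].tolist() == [1.0]
        assert groups["b"].tolist() == [2.0]
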