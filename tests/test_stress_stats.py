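"""Change scores, mixed ANOVA, Holm adjustment, post hocs, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stressrank.stress_stats import (
    CorrelationMethod,
    UndefinedChangeError,
    change_score,
    change_table,
    holm_adjust,
    mixed_anova,
    partial_correlation,
    pearson_correlation,
    posthoc_time_contrasts,
    rank_collapse_correlation,
)


def make_design(rng, n_per_group=(6, 6), k=3, effect=0.5):
    rows = []
    uid = 0
    for g, n in enumerate(n_per_group):
        for _ in range(n):
            uid += 1
            base = rng.normal(g * effect, 1)
            for t in range(k):
                rows.append(
                    {
                        "unit": f"s{uid}",
                        "time": f"T{t}",
                        "group": f"g{g}",
                        "value": base + effect * t + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


class TestChangeScore:
    def test_signed_proportion(self):
        assert change_score(110, 100) == pytest.approx(0.10)

    @given(st.floats(min_value=-1e6, max_value=1e6).filter(lambda v: abs(v) > 1e-9))
    @settings(max_examples=50, derandomize=True)
    def test_identity_change_is_zero(self, x):
        assert change_score(x, x) == 0.0

    @given(
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.1, max_value=100),
        st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, xi, xj, c):
        assert change_score(c * xi, c * xj) == pytest.approx(change_score(xi, xj))

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedChangeError):
            change_score(5, 0)

    def test_change_table_flags_undefined_as_missing(self, caplog):
        wide = pd.DataFrame({"S1": [100.0, 0.0], "S2": [110.0, 4.0]}, index=["a", "b"])
        tab = change_table(wide)
        assert tab.loc["a", "S2vs1"] == pytest.approx(0.10)
        assert np.isnan(tab.loc["b", "S2vs1"])


class TestMixedAnova:
    def test_constant_data_yields_zero_f(self):
        df = make_design(np.random.default_rng(0), effect=0.0)
        df["value"] = 7.0
        res = mixed_anova(df)
        assert (res.table["F"] == 0).all()
        assert (res.table["partial_eta_sq"] == 0).all()

    def test_two_within_levels_skip_sphericity(self):
        df = make_design(np.random.default_rng(1), k=2)
        res = mixed_anova(df)
        assert res.epsilon == 1.0 and not res.gg_applied
        assert res.mauchly_p == 1.0

    def test_matches_reference_implementation(self):
        """F, df, p and partial eta^2 agree with pingouin on random designs."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        for trial in range(10):
            k = int(rng.integers(2, 5))
            df = make_design(rng, n_per_group=tuple(rng.integers(3, 7, 2)), k=k)
            mine = mixed_anova(df)
            ref = pg.mixed_anova(
                data=df, dv="value", within="time", between="group", subject="unit"
            )
            for eff, row in (("group", ref.iloc[0]), ("time", ref.iloc[1]), ("interaction", ref.iloc[2])):
                got = mine.table.loc[eff]
                assert got["F"] == pytest.approx(row["F"], abs=1e-8)
                assert got["p_unc"] == pytest.approx(row["p_unc"], abs=1e-8)
                assert got["partial_eta_sq"] == pytest.approx(row["np2"], abs=1e-8)
                assert (got["df1"], got["df2"]) == (row["DF1"], row["DF2"])

    def test_single_between_level_reduces_to_paired_t(self):
        """With one group and two time levels, the time F equals t^2."""
        rng = np.random.default_rng(3)
        wide = rng.normal(size=(8, 2)) + [0, 0.8]
        rows = [
            {"unit": f"s{i}", "time": f"T{t}", "group": "all", "value": wide[i, t]}
            for i in range(8)
            for t in range(2)
        ]
        res = mixed_anova(pd.DataFrame(rows))
        t = stats.ttest_rel(wide[:, 0], wide[:, 1]).statistic
        assert res.table.loc["time", "F"] == pytest.approx(t**2, rel=1e-10)

    def test_unbalanced_within_rejected(self):
        df = make_design(np.random.default_rng(4))
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="no complete units|unbalanced|fewer than 2"):
            mixed_anova(df.iloc[:3])

    def test_singleton_between_level_rejected(self):
        df = make_design(np.random.default_rng(5), n_per_group=(5, 1))
        with pytest.raises(ValueError, match="fewer than 2 units"):
            mixed_anova(df)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.04]), [0.04])

    def test_hand_enumeration(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(holm_adjust(p), sm.multipletests(p, method="holm")[1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    @settings(max_examples=50, derandomize=True)
    def test_adjusted_never_below_raw_and_permutation_invariant(self, p):
        p = np.array(p)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(p * len(p), 1) + 1e-12)  # never above full Bonferroni cap
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(holm_adjust(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestPosthoc:
    def test_identical_values_give_null_result(self):
        wide = pd.DataFrame({"S1": [1.0, 2, 3], "S2": [1.0, 2, 3]})
        res = posthoc_time_contrasts(wide)
        assert res.loc[0, "t"] == 0.0 and res.loc[0, "p_raw"] == 1.0

    def test_two_timepoints_equal_direct_paired_t(self):
        rng = np.random.default_rng(7)
        wide = pd.DataFrame({"S1": rng.normal(size=9), "S2": rng.normal(0.5, 1, size=9)})
        res = posthoc_time_contrasts(wide)
        ref = stats.ttest_rel(wide["S2"], wide["S1"])
        assert res.loc[0, "t"] == pytest.approx(ref.statistic)
        assert res.loc[0, "p_raw"] == pytest.approx(ref.pvalue)
        assert res.loc[0, "p_holm"] == pytest.approx(ref.pvalue)  # family of one

    def test_three_timepoints_enumerate_three_contrasts(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame({f"S{i}": rng.normal(size=6) for i in (1, 2, 3)})
        res = posthoc_time_contrasts(wide)
        assert sorted(res["contrast"]) == ["S2vs1", "S3vs1", "S3vs2"]

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            posthoc_time_contrasts(pd.DataFrame({"S1": [1.0], "S2": [2.0]}))


class TestRankCollapse:
    def test_concordant_groups_give_unit_correlation(self):
        groups = {"A": ([1, 2, 3, 4], [10, 20, 30, 40]), "B": ([5, 1, 3], [50, 10, 30])}
        res = rank_collapse_correlation(groups)
        assert res.r == pytest.approx(1.0)
        assert res.method is CorrelationMethod.RANK_COLLAPSED

    def test_invariant_under_monotone_within_group_transform(self):
        rng = np.random.default_rng(9)
        x = {"A": rng.normal(size=6), "B": rng.normal(size=5)}
        y = {"A": rng.normal(size=6), "B": rng.normal(size=5)}
        base = rank_collapse_correlation({g: (x[g], y[g]) for g in x})
        warped = rank_collapse_correlation({g: (np.exp(3 * x[g]), y[g]) for g in x})
        assert warped.r == pytest.approx(base.r)
        assert warped.p == pytest.approx(base.p)

    def test_two_groups_of_four_match_hand_oracle(self):
        """Rank within groups, pool, Pearson — recomputed longhand here."""
        groups = {"A": ([3.0, 1, 4, 2], [2.0, 1, 3, 4]), "B": ([9, 7, 8, 6.0], [1.0, 4, 2, 3])}
        pooled_x, pooled_y = [], []
        for gx, gy in groups.values():
            pooled_x.extend(stats.rankdata(gx))
            pooled_y.extend(stats.rankdata(gy))
        expected_r, expected_p = stats.pearsonr(pooled_x, pooled_y)
        res = rank_collapse_correlation(groups)
        assert res.r == pytest.approx(expected_r)
        assert res.p == pytest.approx(expected_p)
        assert res.n == 8

    def test_single_group_equals_spearman(self):
        rng = np.random.default_rng(10)
        x, y = rng.permutation(12).astype(float), rng.normal(size=12)
        res = rank_collapse_correlation({"only": (x, y)})
        assert res.r == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_collapse_correlation({"A": ([1.0, 1, 1, 1], [1.0, 2, 3, 4])})


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle(self):
        """r_xy.z equals the Pearson correlation of OLS residuals on z."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.3 * z + rng.normal(size=n)
            res = partial_correlation(x, y, z)
            rx = x - np.polyval(np.polyfit(z, x, 1), z)
            ry = y - np.polyval(np.polyfit(z, y, 1), z)
            assert res.r == pytest.approx(stats.pearsonr(rx, ry).statistic, abs=1e-10)

    def test_uncorrelated_control_leaves_r_unchanged(self):
        # orthogonalize z against x and y so r_xz = r_yz = 0 exactly
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        z = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, y])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_control_identical_to_x_rejected(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=10), rng.normal(size=10)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            partial_correlation(x, y, x)

    def test_p_uses_n_minus_3_degrees_of_freedom(self):
        rng = np.random.default_rng(14)
        x, y, z = rng.normal(size=(3, 15))
        res = partial_correlation(x, y, z)
        t = res.r * np.sqrt((15 - 3) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 12))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            partial_correlation([1, 2, 3], [2, 1, 3], [1, 3, 2])


def test_pearson_drops_missing_pairwise():
    x = np.array([1.0, 2, np.nan, 4, 5, 6])
    y = np.array([2.0, 4, 6, np.nan, 10, 12])
    res = pearson_correlation(x, y)
    assert res.n == 4 and res.r == pytest.approx(1.0)
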