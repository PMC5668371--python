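"""Layer assignment, bins, chi-square, t-tests, ANOVA, percent change."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v1aging.groupstats import (
    DEFAULT_BIN_SPECS,
    assign_layer,
    bin_distribution,
    chi_square_test,
    percent_change,
    summarize_group,
    t_test,
    two_way_anova,
)


def pearson_oracle(table: np.ndarray) -> tuple[float, int]:
    """Brute-force Pearson statistic: sum (O-E)^2/E with margin-product E."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, dof


def anova_ss_oracle(values, age, layer):
    """From-scratch sum-of-squares decomposition for a balanced design."""
    import pandas as pd

    df = pd.DataFrame({"v": values, "a": age, "l": layer})
    grand = df["v"].mean()
    n = len(df)
    a_means = df.groupby("a")["v"].mean()
    l_means = df.groupby("l")["v"].mean()
    cell_means = df.groupby(["a", "l"])["v"].mean()
    na = df["a"].nunique()
    nl = df["l"].nunique()
    reps = n // (na * nl)
    ss_a = reps * nl * ((a_means - grand) ** 2).sum()
    ss_l = reps * na * ((l_means - grand) ** 2).sum()
    ss_cells = reps * ((cell_means - grand) ** 2).sum()
    ss_int = ss_cells - ss_a - ss_l
    ss_tot = ((df["v"] - grand) ** 2).sum()
    ss_err = ss_tot - ss_cells
    df_err = n - na * nl
    f_a = (ss_a / (na - 1)) / (ss_err / df_err)
    return float(f_a), na - 1, df_err


class TestAssignLayer:
    @pytest.mark.parametrize(
        "depth,layer",
        [(0, "I"), (99.9, "I"), (100, "II-III"), (500, "IV"), (699.9, "IV"),
         (700, "V"), (1100, "VI"), (1500, "VI")],
    )
    def test_boundaries(self, depth, layer):
        assert assign_layer(depth) == layer

    def test_out_of_range_depth_rejected(self):
        with pytest.raises(ValueError):
            assign_layer(1500.1)
        with pytest.raises(ValueError):
            assign_layer(-1.0)


class TestBins:
    def test_printed_dsi_distribution(self):
        """Counts 59/14/10 of n=83 reproduce the reported 71.1/16.9/12.0%."""
        values = [0.1] * 59 + [0.5] * 14 + [0.9] * 10
        counts, pct = bin_distribution(values, DEFAULT_BIN_SPECS["dsi"])
        assert list(counts) == [59, 14, 10]
        assert list(pct) == [71.1, 16.9, 12.0]

    def test_all_values_in_one_bin(self):
        _, pct = bin_distribution([0.1, 0.2, 0.3], DEFAULT_BIN_SPECS["osi"])
        assert list(pct) == [100.0, 0.0, 0.0]

    @pytest.mark.parametrize(
        "metric,value,idx",
        [("osi", 0.4, 0), ("osi", 0.65, 2), ("dsi", 0.6, 2), ("or", 60.0, 0),
         ("ar", 30.0, 1), ("sa", 5.0, 1), ("sa", 10.0, 1), ("snr", 10.0, 1)],
    )
    def test_boundary_inclusivity_as_printed(self, metric, value, idx):
        assert DEFAULT_BIN_SPECS[metric].index_of(value) == idx

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, values):
        _, pct = bin_distribution(values, DEFAULT_BIN_SPECS["osi"])
        assert abs(pct.sum() - 100.0) <= 0.1 + 1e-9


class TestChiSquare:
    def test_hand_computed_2x2(self):
        stat, dof, p = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(20.0 / 3.0, abs=1e-3)
        assert dof == 1

    def test_identical_rows_give_zero_statistic(self):
        stat, _, p = chi_square_test([[5, 7, 9], [5, 7, 9]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [1, 2]])

    def test_exhaustive_2x2_tables_match_oracle(self):
        for a in range(1, 6):
            for b in range(1, 6):
                for c in range(1, 6):
                    for d in range(1, 6):
                        table = [[a, b], [c, d]]
                        stat, dof, _ = chi_square_test(table)
                        o_stat, o_dof = pearson_oracle(table)
                        assert stat == pytest.approx(o_stat, rel=1e-12)
                        assert dof == o_dof

    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=6,
                    max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_2x3_tables_match_oracle(self, cells):
        table = np.array(cells).reshape(2, 3)
        stat, dof, _ = chi_square_test(table)
        o_stat, o_dof = pearson_oracle(table)
        assert stat == pytest.approx(o_stat, rel=1e-12)
        assert dof == o_dof == 2


class TestTTest:
    def test_identical_samples(self):
        t, _, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_hand_computation(self):
        t, df, _ = t_test([1, 2, 3], [2, 3, 4], variant="pooled")
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4)

    def test_one_tailed_is_half_two_tailed(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        _, _, p2 = t_test(a, b, tails=2)
        _, _, p1 = t_test(a, b, tails=1)
        assert p1 == pytest.approx(p2 / 2)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0])


class TestAnova:
    def _balanced_toy(self):
        rng = np.random.default_rng(3)
        rows = []
        for age, shift in (("young", 0.0), ("old", 4.0)):
            for layer in "ABCDE":
                for _ in range(6):
                    rows.append((rng.normal(shift + ord(layer) * 0.1), age, layer))
        v, a, l = zip(*rows)
        return list(v), list(a), list(l)

    def test_all_equal_observations_give_zero_f(self):
        v = [1.0] * 20
        a = ["y"] * 10 + ["o"] * 10
        l = (["L1"] * 5 + ["L2"] * 5) * 2
        effects = two_way_anova(v, a, l)
        assert effects["age"][0] == 0.0

    def test_matches_sum_of_squares_oracle(self):
        v, a, l = self._balanced_toy()
        F, df1, df2, p = two_way_anova(v, a, l)["age"]
        oF, odf1, odf2 = anova_ss_oracle(v, a, l)
        assert F == pytest.approx(oF, rel=1e-9)
        assert (df1, df2) == (odf1, odf2)
        assert p < 0.0001  # planted age effect is large

    def test_single_level_second_factor_reduces_to_one_way(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 12)
        b = rng.normal(2, 1, 12)
        v = np.concatenate([a, b])
        age = ["y"] * 12 + ["o"] * 12
        layer = ["only"] * 24
        F, df1, df2, p = two_way_anova(v, age, layer)["age"]
        from scipy.stats import f_oneway

        oF, op = f_oneway(a, b)
        assert F == pytest.approx(float(oF), rel=1e-12)
        assert (df1, df2) == (1, 22)

    def test_unbalanced_design_rejected(self):
        v = [1.0] * 11
        a = ["y"] * 6 + ["o"] * 5
        l = ["L1", "L2"] * 5 + ["L1"]
        with pytest.raises(ValueError, match="alanced"):
            two_way_anova(v, a, l)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,cmp,expected",
        [(47.1, 99.1, 110.4), (21.9, 61.5, 180.8), (18.3, 5.2, -71.6),
         (82.6, 29.1, -64.8), (5.0, 5.0, 0.0)],
    )
    def test_reported_style_changes(self, ref, cmp, expected):
        assert percent_change(ref, cmp, decimals=1) == expected

    def test_nearest_integer_rounding(self):
        assert percent_change(3.4, 24.7, decimals=0) == 626.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @given(st.floats(min_value=0.1, max_value=1e4),
           st.floats(min_value=-90, max_value=500))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_property(self, x, p):
        assert percent_change(x, x * (1 + p / 100.0), decimals=6) == \
            pytest.approx(p, abs=1e-4)


class TestSummaries:
    def test_toy_mean_and_sd(self):
        s = summarize_group([1.0, 2.0, 3.0])
        assert (s.mean, s.sd, s.n) == (2.0, 1.0, 3)

    def test_single_value_warns_with_zero_sd(self):
        with pytest.warns(UserWarning):
            s = summarize_group([4.2])
        assert (s.mean, s.sd, s.n) == (4.2, 0.0, 1)

    def test_nan_entries_excluded_from_n(self):
        s = summarize_group([1.0, np.nan, 3.0])
        assert s.n == 2 and s.mean == 2.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([np.nan])
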