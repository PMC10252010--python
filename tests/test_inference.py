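"""Factorial ANOVA, Tukey–Kramer, letters, correlations, assumptions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zoometry.inference import (
    DegenerateDesignError,
    assumption_checks,
    compact_letter_display,
    one_way_anova,
    pearson_matrix,
    tukey_kramer,
    two_way_anova,
)

# Fixed 12-row worked factorial (3 x 2, unbalanced).  The expected Type II
# sums of squares / F / p were computed once with an independent
# model-comparison oracle (OLS fits of the nested models) and frozen.
WORKED_ROWS = [
    ("NEGRO", "FEMALE", 124.1), ("NEGRO", "FEMALE", 125.3),
    ("NEGRO", "FEMALE", 123.0), ("NEGRO", "MALE", 127.2),
    ("NEGRO", "MALE", 126.1), ("CALLEJON", "FEMALE", 124.9),
    ("CALLEJON", "FEMALE", 126.0), ("CALLEJON", "MALE", 128.4),
    ("CALLEJON", "MALE", 127.0), ("ATIGRADO", "FEMALE", 123.5),
    ("ATIGRADO", "FEMALE", 125.1), ("ATIGRADO", "MALE", 126.9),
]
WORKED = pd.DataFrame(WORKED_ROWS, columns=["biotype", "sex", "y"])
WORKED_TYPE2 = {
    "biotype": (3.3682823920, 2, 1.6520186119, 0.2681880567),
    "sex": (17.1093062016, 1, 16.7829706609, 0.0063809777),
    "biotype:sex": (0.0601937984, 2, 0.0295228439, 0.9710488300),
}


class TestTwoWayAnova:
    def test_worked_example_type2(self):
        result = two_way_anova(WORKED, "y", ss_type=2)
        table = result.table.set_index("term")
        for term, (ss, df, f_stat, p) in WORKED_TYPE2.items():
            row = table.loc[term]
            assert row.ss == pytest.approx(ss, abs=1e-8)
            assert row.df == df
            assert row.F == pytest.approx(f_stat, abs=1e-8)
            assert row.p == pytest.approx(p, abs=1e-8)
        assert table.loc["residual", "df"] == 6

    def test_dfs_sum_to_n_minus_1(self):
        result = two_way_anova(WORKED, "y")
        assert result.table["df"].sum() == len(WORKED) - 1

    def test_type1_decomposes_total_ss_exactly(self):
        result = two_way_anova(WORKED, "y", ss_type=1)
        assert result.table["ss"].sum() == pytest.approx(
            result.table.attrs["ss_total"], rel=1e-12
        )

    def test_types_agree_on_balanced_design(self):
        rng = np.random.default_rng(5)
        rows = [
            (a, b, rng.normal())
            for a in "xyz" for b in "uv" for _ in range(4)
        ]
        balanced = pd.DataFrame(rows, columns=["biotype", "sex", "y"])
        tables = {
            t: two_way_anova(balanced, "y", ss_type=t).table.set_index("term")
            for t in (1, 2, 3)
        }
        for term in ("biotype", "sex", "biotype:sex"):
            ss = {t: tables[t].loc[term, "ss"] for t in (1, 2, 3)}
            assert ss[1] == pytest.approx(ss[2], rel=1e-10)
            assert ss[1] == pytest.approx(ss[3], rel=1e-10)

    def test_f_equals_squared_t_for_two_balanced_groups(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        frame = pd.DataFrame({
            "biotype": ["A"] * 10 + ["B"] * 10,
            "y": np.concatenate([a, b]),
        })
        result = one_way_anova(frame, "y")
        t_stat, t_p = stats.ttest_ind(a, b)
        row = result.table.set_index("term").loc["biotype"]
        assert row.F == pytest.approx(t_stat**2, rel=1e-10)
        assert row.p == pytest.approx(t_p, rel=1e-10)

    def test_constant_response_reports_nan_with_warning(self):
        frame = WORKED.assign(y=5.0)
        with pytest.warns(UserWarning, match="zero residual"):
            result = two_way_anova(frame, "y")
        table = result.table.set_index("term")
        assert table.loc["biotype", "ss"] == pytest.approx(0.0, abs=1e-20)
        assert math.isnan(table.loc["biotype", "p"])

    def test_empty_cell_raises_with_fallback_available(self):
        broken = WORKED[~((WORKED.biotype == "ATIGRADO")
                          & (WORKED.sex == "MALE"))]
        with pytest.raises(DegenerateDesignError, match="empty design cell"):
            two_way_anova(broken, "y")
        result = two_way_anova(broken, "y", allow_empty_cells=True)
        assert "biotype:sex" not in set(result.table["term"])

    def test_single_level_factor_rejected(self):
        frame = WORKED.assign(sex="FEMALE")
        with pytest.raises(DegenerateDesignError):
            two_way_anova(frame, "y")


class TestTukeyKramer:
    def test_identical_groups_share_one_letter(self):
        sample = np.array([1.0, 2.0, 3.0, 4.0])
        result = tukey_kramer({"a": sample, "b": sample, "c": sample})
        assert (result.pairs["p_adj"] > 0.999).all()
        assert set(result.letters.values()) == {"a"}

    def test_two_groups_reduce_to_pooled_t(self):
        # with k = 2 the range statistic is sqrt(2)|t| and the adjusted
        # p equals the unadjusted pooled-variance two-sample p
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 12)
        result = tukey_kramer({"x": x, "y": y})
        t_stat, t_p = stats.ttest_ind(x, y)
        row = result.pairs.iloc[0]
        assert row.q == pytest.approx(math.sqrt(2) * abs(t_stat), rel=1e-10)
        assert row.p_adj == pytest.approx(t_p, rel=1e-6)

    def test_zero_variance_identical_means(self):
        sample = np.full(5, 2.0)
        result = tukey_kramer({"a": sample, "b": sample})
        assert (result.pairs["p_adj"] == 1.0).all()
        assert set(result.letters.values()) == {"a"}

    def test_pair_count(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(size=5) for i in range(5)}
        result = tukey_kramer(groups)
        assert len(result.pairs) == 5 * 4 // 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer({"a": np.arange(4.0)})

    def test_letters_match_significance(self):
        rng = np.random.default_rng(9)
        groups = {
            "lo": rng.normal(0, 1, 30),
            "mid": rng.normal(1.0, 1, 30),
            "hi": rng.normal(5.0, 1, 30),
        }
        result = tukey_kramer(groups)
        for _, row in result.pairs.iterrows():
            shared = set(result.letters[row.group1]) & set(
                result.letters[row.group2]
            )
            assert bool(shared) == (row.p_adj > result.alpha)


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], {})
        assert set(letters.values()) == {"a"}

    def test_chain_pattern(self):
        # x != z only: x=a, z=b, y shares both
        letters = compact_letter_display(
            ["x", "y", "z"], {("x", "z"): True}
        )
        assert letters["x"] != letters["z"]
        assert set(letters["y"]) == set(letters["x"]) | set(letters["z"])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_share_letter_iff_not_significant_exhaustive(self, k):
        names = [f"g{i}" for i in range(k)]
        pairs = list(itertools.combinations(names, 2))
        for bits in itertools.product([False, True], repeat=len(pairs)):
            sig = dict(zip(pairs, bits))
            letters = compact_letter_display(names, sig)
            for (a, b), is_sig in sig.items():
                shared = set(letters[a]) & set(letters[b])
                assert bool(shared) != is_sig, (sig, letters)


class TestPearsonMatrix:
    def test_exact_linear_relation(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        frame["y"] = 2.0 * frame.x + 1.0
        matrix = pearson_matrix(frame)
        assert matrix.r.loc["x", "y"] == pytest.approx(1.0)
        assert matrix.p.loc["x", "y"] == 0.0

    def test_three_point_hand_example(self):
        # cov = 0.5, sx = sy = 1 -> r = 0.5
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 3.0, 2.0]})
        matrix = pearson_matrix(frame)
        assert matrix.r.loc["x", "y"] == pytest.approx(0.5, rel=1e-12)
        _, p_ref = stats.pearsonr(frame.x, frame.y)
        assert matrix.p.loc["x", "y"] == pytest.approx(p_ref, rel=1e-9)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(10)
        frame = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        matrix = pearson_matrix(frame)
        for i, j in itertools.combinations("abcd", 2):
            r_ref, p_ref = stats.pearsonr(frame[i], frame[j])
            assert matrix.r.loc[i, j] == pytest.approx(r_ref, abs=1e-12)
            assert matrix.p.loc[i, j] == pytest.approx(p_ref, rel=1e-9)

    def test_symmetry_unit_diagonal_bounds(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.normal(size=(25, 5)),
                             columns=list("abcde"))
        matrix = pearson_matrix(frame)
        r = matrix.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0).all()

    def test_zero_variance_gives_nan(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        matrix = pearson_matrix(frame)
        assert math.isnan(matrix.r.loc["x", "y"])

    def test_pairwise_complete(self):
        frame = pd.DataFrame({
            "x": [1.0, 2.0, 3.0, 4.0, None],
            "y": [1.0, 2.1, 2.9, 4.2, 5.0],
        })
        matrix = pearson_matrix(frame)
        assert matrix.n.loc["x", "y"] == 4

    def test_bonferroni_and_holm(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        raw = pearson_matrix(frame)
        bonf = pearson_matrix(frame, adjust="bonferroni")
        holm = pearson_matrix(frame, adjust="holm")
        m = 6  # pairs
        for i, j in itertools.combinations("abcd", 2):
            assert bonf.p.loc[i, j] == pytest.approx(
                min(raw.p.loc[i, j] * m, 1.0), rel=1e-12
            )
            assert holm.p.loc[i, j] <= bonf.p.loc[i, j] + 1e-12
            assert holm.p.loc[i, j] >= raw.p.loc[i, j] - 1e-12


class TestAssumptionChecks:
    def test_inflated_variance_group_detected(self):
        rng = np.random.default_rng(13)
        groups = {
            "a": rng.normal(0, 1, 200),
            "b": rng.normal(0, 1, 200),
            "c": rng.normal(0, 10, 200),
        }
        report = assumption_checks(groups)
        levene = report[report.check == "brown_forsythe"].iloc[0]
        assert levene.p < 0.001 and levene.flag == "heteroscedastic"

    def test_type_one_error_rate_near_alpha(self):
        """Identical normal populations are rejected at ~alpha."""
        rng = np.random.default_rng(14)
        reps = 200
        rejections = 0
        for _ in range(reps):
            groups = {g: rng.normal(0, 1, 20) for g in "abc"}
            report = assumption_checks(groups)
            levene = report[report.check == "brown_forsythe"].iloc[0]
            rejections += levene.p <= 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.05)

    def test_constant_group_flagged_not_crashed(self):
        groups = {"a": np.full(5, 3.0), "b": np.random.default_rng(15).normal(size=5)}
        report = assumption_checks(groups)
        shapiro_a = report[(report.check == "shapiro_wilk")
                           & (report.group == "a")].iloc[0]
        assert shapiro_a.flag == "constant group"

    def test_tiny_group_flagged(self):
        report = assumption_checks({"a": np.array([1.0, 2.0])})
        assert "too few" in report.iloc[0].flag
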