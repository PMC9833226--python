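import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhscreen import ContingencyTable, chi_square, mann_whitney, quartiles
from fhscreen.stats_engine import format_p

from _oracles import exact_mann_whitney_p, pearson_chi2


class TestChiSquare:
    def test_hypertension_table_reproduces_published_p(self):
        r = chi_square([[32, 23], [83, 24]])
        assert round(r.p_two_sided, 3) == 0.010
        assert r.df == 1

    def test_diabetes_table_reproduces_published_p(self):
        r = chi_square([[9, 46], [18, 89]])
        assert round(r.p_two_sided, 3) == 0.941

    def test_identical_row_proportions_give_zero_statistic(self):
        r = chi_square([[10, 20], [30, 60]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 7]])

    def test_degenerate_table_shapes_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(((1, 2),))
        with pytest.raises(ValueError):
            ContingencyTable(((1,), (2,)))
        with pytest.raises(ValueError):
            ContingencyTable(((1, -2), (3, 4)))

    @given(
        cells=st.lists(st.integers(1, 50), min_size=6, max_size=6),
        seed=st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_permutation_and_transposition(self, cells, seed):
        table = np.array(cells).reshape(2, 3)
        base = chi_square(table.tolist()).statistic
        perm = table[:, [2, 0, 1]]
        assert chi_square(perm.tolist()).statistic == pytest.approx(base)
        assert chi_square(table.T.tolist()).statistic == pytest.approx(base)
        # and the statistic matches the closed-form Pearson sum
        stat, df = pearson_chi2(table)
        assert base == pytest.approx(stat)

    @given(cells=st.lists(st.integers(1, 80), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_2x2_statistic_equals_squared_two_proportion_z(self, cells):
        a, b, c, d = cells
        r = chi_square([[a, b], [c, d]])
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        p = (a + c) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert r.statistic == pytest.approx(z**2, rel=1e-9)


class TestMannWhitney:
    def test_maximal_separation_exact_p(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_two_sided == pytest.approx(0.1)
        assert r.method == "mann-whitney-exact"

    def test_identical_samples_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert r.p_two_sided == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.8, 1, 7)
            r = mann_whitney(a, b)
            assert r.p_two_sided == pytest.approx(exact_mann_whitney_p(a, b))

    def test_normal_approximation_converges_at_n8(self):
        """|p_approx - p_exact| < 0.02 for untied samples of 8 + 8."""
        from scipy import stats

        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 1, 8)
            p_exact = exact_mann_whitney_p(a, b)
            p_approx = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
            assert abs(p_approx - p_exact) < 0.02

    def test_large_tied_sample_matches_permutation_estimate(self):
        """Tie-corrected approximation vs a 1e5-resample permutation null."""
        rng = np.random.default_rng(123)
        a = np.round(rng.normal(5.4, 0.4, 30), 1)  # rounding induces ties
        b = np.round(rng.normal(5.7, 0.4, 30), 1)
        r = mann_whitney(a, b)
        assert r.method == "mann-whitney-normal-approx"

        from scipy.stats import rankdata

        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        u_obs = ranks[:30].sum() - 30 * 31 / 2
        B = 100_000
        perm = rng.permuted(np.tile(ranks, (B, 1)), axis=1)
        u_perm = perm[:, :30].sum(axis=1) - 30 * 31 / 2
        mean = 30 * 30 / 2
        p_mc = np.mean(np.abs(u_perm - mean) >= abs(u_obs - mean) - 1e-9)
        assert r.p_two_sided == pytest.approx(p_mc, abs=0.01)


class TestQuartiles:
    @pytest.mark.parametrize(
        "values,expected",
        [
            # hand-computed with linear interpolation between order stats
            ([1, 2, 3, 4], (1.75, 2.5, 3.25)),
            ([1, 2, 3, 4, 5], (2.0, 3.0, 4.0)),
            ([1, 2, 3, 4, 5, 6, 7], (2.5, 4.0, 5.5)),
        ],
    )
    def test_linear_interpolation_convention(self, values, expected):
        assert quartiles(values) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            quartiles([])


class TestFormatting:
    @pytest.mark.parametrize(
        "p,text",
        [(0.0104, "0.010"), (0.9409, "0.941"), (0.0004, "<0.001"),
         (0.0005, "0.001"), (1.0, "1.000")],
    )
    def test_p_value_table_style(self, p, text):
        assert format_p(p) == text


class TestBaselineTable:
    def test_fixture_family_history_row(self, fixture_decisions):
        from fhscreen import baseline_table

        table = baseline_table(fixture_decisions, by="dlcn")
        row = table[table["variable"] == "Family history of early CAD"].iloc[0]
        assert "2 (3.6%)" in row.iloc[1]
        assert "101 (94.4%)" in row.iloc[2]
        assert row["p_value"] == "<0.001"

    def test_fixture_hypertension_p_value(self, fixture_decisions):
        from fhscreen import baseline_table

        table = baseline_table(fixture_decisions, by="dlcn")
        row = table[table["variable"] == "Hypertension"].iloc[0]
        assert row["p_value"] == "0.010"

    def test_single_group_percentages_sum_to_100(self, fixture_decisions):
        from fhscreen import baseline_table

        table = baseline_table(fixture_decisions, by="dlcn")
        smoking = table[table["variable"].str.startswith("  ")]
        for col in table.columns[1:3]:
            pcts = (
                smoking[smoking["variable"].isin(
                    ["  non-smoker", "  ex-smoker", "  current"])][col]
                .str.extract(r"\((\d+\.\d)%\)")[0].astype(float)
            )
            assert pcts.sum() == pytest.approx(100.0, abs=0.2)

    def test_genetic_partition_splits_analyzed(self, fixture_decisions):
        from fhscreen import baseline_table

        table = baseline_table(fixture_decisions, by="genetic")
        cols = table.columns
        assert "no genetic testing (n=141)" in cols[1]
        assert "genetic testing (n=21)" in cols[2]
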