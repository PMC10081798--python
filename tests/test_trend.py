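import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ngramtrends._bruteforce import pearson_reference, rolling_mean_reference
from ngramtrends.normalize import CompositeSeries
from ngramtrends.trend import (
    RollingSeries,
    TrendError,
    correlation_matrix,
    pearson,
    rolling_mean,
    stars_for,
    trend_label,
)


def comp(construct, values, language="pooled", year_start=1970):
    values = np.asarray(values, float)
    years = np.arange(year_start, year_start + len(values))
    return CompositeSeries(construct, language, years, values, n_words=1)


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0, abs=1e-12)
        # one t-test dof at n=3: even r ~ 1 leaves p ~ 1e-8, not 0
        assert res.p < 1e-6

    def test_perfect_anti_linearity(self):
        assert pearson([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0, abs=1e-12)

    def test_fixed_series_match_sums_formula_oracle(self):
        x = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3]
        y = [2, 7, 1, 8, 2, 8, 1, 8, 2, 8]
        res = pearson(x, y)
        r_ref, p_ref = pearson_reference(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=50),
        st.integers(0, 2**31 - 1),
    )
    def test_random_series_match_oracle(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(xs) + rng.normal(scale=0.5, size=len(xs))
        y = rng.normal(size=len(xs))
        res = pearson(x, y)
        r_ref, p_ref = pearson_reference(x, y)
        assert abs(res.r - r_ref) < 1e-10 and abs(res.p - p_ref) < 1e-10

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-15)
        assert pearson(x, 3.5 * x - 2).r == pytest.approx(1.0, abs=1e-12)
        assert pearson(x, -0.1 * x + 7).r == pytest.approx(-1.0, abs=1e-12)
        r = pearson(x, y).r
        assert pearson(2 * x + 1, y).r == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y,msg",
        [
            ([1, 1, 1], [1, 2, 3], "zero variance"),
            ([1, 2, 3], [1, 2], "shapes"),
            ([1, 2], [3, 4], "n >= 3"),
        ],
    )
    def test_invalid_inputs(self, x, y, msg):
        with pytest.raises(TrendError, match=msg):
            pearson(x, y)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, ""), (0.05, ""), (0.049, "*"), (0.01, "*"), (0.009, "**"),
         (0.001, "**"), (0.0009, "***")],
    )
    def test_star_thresholds(self, p, expected):
        assert stars_for(p) == expected


class TestCorrelationMatrix:
    def test_duplicated_construct_gives_unit_r(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=50)
        m = correlation_matrix([comp("A", v), comp("A-copy", v)])
        assert m.get("A", "A-copy").r == 1.0

    def test_linear_construct_vs_years(self):
        years = np.arange(1970, 2020)
        m = correlation_matrix([comp("lin", 0.3 * (years - 1970) + 1)])
        assert m.get("lin", "Years").r == pytest.approx(1.0, abs=1e-12)

    def test_control_ordered_last_after_years(self):
        rng = np.random.default_rng(3)
        comps = [comp(c, rng.normal(size=20)) for c in
                 ("anxiety", "depression", "religion")]
        m = correlation_matrix(comps, control_construct="religion")
        assert m.labels == ["anxiety", "depression", "Years", "religion"]
        assert len(m.results) + len(m.errors) == 6

    def test_failed_cells_recorded_not_raised(self):
        rng = np.random.default_rng(4)
        comps = [comp("ok", rng.normal(size=10)), comp("flat", np.zeros(10))]
        m = correlation_matrix(comps)
        assert ("flat", "Years") in m.errors or ("ok", "flat") in m.errors
        assert m.get("ok", "Years") is not None

    def test_holm_adjustment_attached_and_ordered(self):
        rng = np.random.default_rng(5)
        comps = [comp(c, rng.normal(size=30)) for c in "abc"]
        m = correlation_matrix(comps)
        for res in m.results.values():
            assert res.holm_p is not None and res.holm_p >= res.p - 1e-15

    def test_mismatched_years_rejected(self):
        with pytest.raises(TrendError, match="year"):
            correlation_matrix(
                [comp("a", np.arange(10.0)),
                 comp("b", np.arange(10.0), year_start=1980)]
            )

    def test_text_table_contains_stars_note(self):
        years = np.arange(1970, 2020)
        m = correlation_matrix([comp("lin", 1.0 * years)])
        text = m.to_text()
        assert "p < .001" in text and "lin" in text


class TestRollingMean:
    def test_window_five_example(self):
        roll = rolling_mean(np.arange(1.0, 11.0), window=5)
        assert np.allclose(roll.values, [3, 4, 5, 6, 7, 8], atol=1e-12)

    def test_window_one_identity(self):
        x = np.array([3.0, 1.0, 4.0])
        assert rolling_mean(x, window=1).values.tolist() == x.tolist()

    def test_short_series_rejected(self):
        with pytest.raises(TrendError, match="shorter"):
            rolling_mean([1.0, 2.0], window=5)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=60),
           st.integers(1, 60))
    def test_matches_bruteforce_loop(self, xs, window):
        if window > len(xs):
            window = len(xs)
        roll = rolling_mean(xs, window=window)
        ref = rolling_mean_reference(xs, window)
        assert len(roll.values) == len(xs) - window + 1
        assert np.allclose(roll.values, ref, atol=1e-12)

    def test_trailing_year_labels(self):
        roll = rolling_mean(np.ones(10), window=5,
                            years=np.arange(1970, 1980))
        assert roll.years[0] == 1974 and roll.years[-1] == 1979

    def test_centered_year_labels(self):
        roll = rolling_mean(np.ones(10), window=5,
                            years=np.arange(1970, 1980), center=True)
        assert roll.years[0] == 1972 and roll.years[-1] == 1977

    def test_pandas_series_carries_years(self, make_panel):
        panel = make_panel({"w": np.linspace(0.1, 1.0, 10)})
        roll = rolling_mean(panel.series("w"), window=3, word="w")
        assert roll.years[0] == 1972 and roll.word == "w"


class TestTrendLabel:
    def _roll(self, values):
        values = np.asarray(values, float)
        return RollingSeries("w", "l", "c", 5, np.arange(len(values)), values)

    def test_strictly_increasing(self):
        assert trend_label(self._roll(np.arange(10.0))) == "increase"

    def test_strictly_decreasing(self):
        assert trend_label(self._roll(-np.arange(10.0))) == "decrease"

    def test_constant_is_flat(self):
        assert trend_label(self._roll(np.ones(10))) == "flat"

    def test_slope_exactly_at_epsilon_is_flat(self):
        values = 0.5 * np.arange(6.0)
        assert trend_label(self._roll(values), slope_epsilon=0.5) == "flat"
        assert trend_label(self._roll(values), slope_epsilon=0.49) == "increase"

    def test_default_epsilon_scales_with_range(self):
        # tiny drift relative to the range stays flat
        values = np.concatenate([[0.0, 100.0], 50 + 0.01 * np.arange(8)])
        assert trend_label(self._roll(values)) == "flat"
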