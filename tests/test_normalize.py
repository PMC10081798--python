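import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ngramtrends._bruteforce import zscore_reference
from ngramtrends.normalize import (
    NormalizeError,
    ZeroVarianceError,
    common_word_adjust,
    composite,
    pool_languages,
    zscore_series,
)
from ngramtrends.synthetic import inflate_panel
from ngramtrends.trend import pearson

finite_series = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=80
).filter(lambda xs: np.std(xs, ddof=1) > 1e-9)


class TestCommonWordAdjust:
    def test_ratio_identity(self, make_panel):
        panel = make_panel({"w": [2.0, 3.0, 4.0], "time": [2.0, 3.0, 4.0]})
        adj = common_word_adjust(panel, "time")
        assert adj.series("w").tolist() == [1.0, 1.0, 1.0]

    def test_common_word_dropped(self, make_panel):
        panel = make_panel({"w": [1.0, 2.0], "time": [5.0, 5.0]})
        assert common_word_adjust(panel, "time").words == ["w"]

    def test_missing_common_word(self, make_panel):
        panel = make_panel({"w": [1.0, 2.0]})
        with pytest.raises(NormalizeError, match="time"):
            common_word_adjust(panel, "time")

    def test_zero_denominator_names_year(self, make_panel):
        panel = make_panel({"w": [1.0, 2.0, 3.0], "time": [5.0, 0.0, 5.0]},
                           year_start=1974)
        with pytest.raises(NormalizeError, match="1975"):
            common_word_adjust(panel, "time")

    def test_yearwise_scaling_cancels(self, make_panel):
        rng = np.random.default_rng(0)
        panel = make_panel(
            {"a": rng.uniform(0.1, 1, 10), "b": rng.uniform(0.1, 1, 10),
             "time": rng.uniform(2, 3, 10)}
        )
        factors = {int(y): float(f)
                   for y, f in zip(panel.years, rng.uniform(0.5, 4, 10))}
        base = common_word_adjust(panel, "time")
        scaled = common_word_adjust(inflate_panel(panel, factors), "time")
        assert np.allclose(base.data, scaled.data, rtol=0, atol=1e-12)


class TestZscore:
    def test_simple_example(self):
        assert zscore_series([1, 2, 3]).tolist() == [-1.0, 0.0, 1.0]

    def test_constant_series_rejected(self):
        with pytest.raises(ZeroVarianceError):
            zscore_series([5.0, 5.0, 5.0])

    def test_too_short_rejected(self):
        with pytest.raises(NormalizeError):
            zscore_series([1.0])

    @given(finite_series)
    def test_matches_two_pass_reference(self, xs):
        z = zscore_series(xs)
        assert np.allclose(z, zscore_reference(xs), atol=1e-10)

    @given(finite_series)
    def test_output_standardized(self, xs):
        z = zscore_series(xs)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9


class TestComposite:
    def test_mean_of_identical_words_is_their_zscore(self, make_panel):
        vals = [0.1, 0.4, 0.2, 0.9]
        panel = make_panel({"a": vals, "b": vals})
        comp = composite(panel, ["a", "b"], construct="c")
        assert np.allclose(comp.values, zscore_series(vals))
        assert comp.n_words == 2

    def test_mirror_words_cancel(self, make_panel):
        z = zscore_series([1.0, 3.0, 2.0, 5.0])
        panel = make_panel({"a": 5 + z, "b": 5 - z})
        comp = composite(panel, ["a", "b"], construct="c")
        assert np.allclose(comp.values, 0.0, atol=1e-12)

    def test_word_order_invariant(self, make_panel):
        rng = np.random.default_rng(3)
        cols = {f"w{i}": rng.uniform(0.1, 1, 8) for i in range(4)}
        panel = make_panel(cols)
        c1 = composite(panel, ["w0", "w1", "w2", "w3"], construct="c")
        c2 = composite(panel, ["w3", "w1", "w0", "w2"], construct="c")
        assert np.allclose(c1.values, c2.values)

    def test_zero_variance_word_dropped_with_policy(self, make_panel):
        panel = make_panel({"live": [0.1, 0.3, 0.2], "dead": [0.0, 0.0, 0.0]})
        comp = composite(panel, ["live", "dead"], construct="c")
        assert comp.n_words == 1 and comp.dropped_words == ("dead",)
        with pytest.raises(ZeroVarianceError):
            composite(panel, ["live", "dead"], construct="c",
                      zero_variance_policy="fail")

    def test_all_zero_variance_rejected(self, make_panel):
        panel = make_panel({"dead": [0.0, 0.0, 0.0]})
        with pytest.raises(NormalizeError, match="positive variance"):
            composite(panel, ["dead"], construct="c")

    def test_missing_word_rejected(self, make_panel):
        panel = make_panel({"a": [1.0, 2.0]})
        with pytest.raises(NormalizeError, match="ghost"):
            composite(panel, ["a", "ghost"], construct="c")

    def test_single_language_composite_mean_zero(self, small_dataset):
        truth = small_dataset.truth
        adj = common_word_adjust(small_dataset.panels["en-GB-2019"],
                                 truth.common_word)
        words = [w for w, c in small_dataset.word_constructs.items() if c == "a"]
        comp = composite(adj, words, construct="a")
        assert abs(comp.values.mean()) < 1e-9

    def test_sum_vs_mean_leave_correlations_unchanged(self, make_panel):
        rng = np.random.default_rng(11)
        cols = {f"w{i}": rng.uniform(0.1, 1, 20) for i in range(5)}
        panel = make_panel(cols)
        third = rng.normal(size=20)
        words = list(cols)
        r_mean = pearson(composite(panel, words, construct="c").values, third).r
        r_sum = pearson(
            composite(panel, words, construct="c", aggregation="sum").values, third
        ).r
        assert abs(r_mean - r_sum) < 1e-12


class TestPoolLanguages:
    def test_single_language_identity(self, make_panel):
        panel = make_panel({"a": [0.2, 0.5, 0.1]})
        comp = composite(panel, ["a"], construct="c")
        pooled = pool_languages([comp])
        assert np.allclose(pooled.values, comp.values)
        assert pooled.language == "pooled" and pooled.n_languages == 1

    def test_identical_composites_pool_to_same(self, make_panel):
        p1 = make_panel({"a": [0.2, 0.5, 0.1]}, language="en-GB-2019")
        p2 = make_panel({"a": [0.2, 0.5, 0.1]}, language="de-2019")
        c1 = composite(p1, ["a"], construct="c")
        c2 = composite(p2, ["a"], construct="c")
        pooled = pool_languages([c1, c2])
        assert np.allclose(pooled.values, c1.values)
        assert pooled.n_languages == 2

    def test_mixed_constructs_rejected(self, make_panel):
        panel = make_panel({"a": [0.2, 0.5, 0.1]})
        c1 = composite(panel, ["a"], construct="x")
        c2 = composite(panel, ["a"], construct="y")
        with pytest.raises(NormalizeError, match="mixed"):
            pool_languages([c1, c2])

    def test_mismatched_years_rejected(self, make_panel):
        c1 = composite(make_panel({"a": [0.2, 0.5, 0.1]}), ["a"], construct="c")
        c2 = composite(make_panel({"a": [0.2, 0.5, 0.1]}, year_start=1980),
                       ["a"], construct="c")
        with pytest.raises(NormalizeError, match="year"):
            pool_languages([c1, c2])

    def test_pooled_series_tracks_shared_latent(self):
        from ngramtrends.synthetic import ConstructSpec, SyntheticTruth, generate_panel

        truth = SyntheticTruth(
            seed=21,
            n_years=50,
            languages=("en-GB-2019", "de-2019", "es-2019", "ru-2019",
                       "fr-2019", "it-2019"),
            constructs={"a": ConstructSpec(8, latent_loading=0.9)},
            noise_sd=0.2,
        )
        ds = generate_panel(truth)
        comps = []
        for lang in truth.languages:
            adj = common_word_adjust(ds.panels[lang], truth.common_word)
            comps.append(composite(adj, adj.words, construct="a"))
        pooled = pool_languages(comps)
        # noise-free limit of the composite is the exponentiated latent path
        noise_free = zscore_series(np.exp(0.9 * ds.latent_path))
        assert pearson(pooled.values, noise_free).r > 0.98
        # and it still tracks the latent path itself strongly (monotone link)
        assert pearson(pooled.values, ds.latent_path).r > 0.85


class TestInfluxInvariance:
    def test_composite_invariant_under_inflation(self, small_dataset):
        truth = small_dataset.truth
        panel = small_dataset.panels["en-GB-2019"]
        rng = np.random.default_rng(17)
        factors = {int(y): float(f)
                   for y, f in zip(panel.years, rng.uniform(0.2, 5.0, len(panel.years)))}
        words = [w for w in panel.words if w != truth.common_word]
        base = composite(common_word_adjust(panel, truth.common_word),
                         words, construct="all")
        inflated = composite(
            common_word_adjust(inflate_panel(panel, factors), truth.common_word),
            words, construct="all",
        )
        assert np.abs(base.values - inflated.values).max() < 1e-9
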