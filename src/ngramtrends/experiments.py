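"""Self-validation experiments for the composite-index pipeline.

Each function here runs the *package's own* implementation on synthetic
inputs and measures a property a correct implementation must have — oracle
agreement, invariance to corpus influx, insensitivity to the sum-vs-mean
aggregation choice, calibrated type-I error under an independent null,
recovery of a known latent correlation, and exact behaviour on degenerate
inputs.  The brute-force counterparts live in :mod:`ngramtrends._bruteforce`
and share no code with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import _bruteforce as bf
from .ngram_io import FrequencyPanel
from .normalize import common_word_adjust, composite, zscore_series
from .synthetic import ConstructSpec, SyntheticTruth, generate_panel, inflate_panel
from .trend import correlation_matrix, pearson, rolling_mean

__all__ = [
    "oracle_deviations",
    "influx_invariance_max_diff",
    "aggregation_max_r_diff",
    "type1_error_rate",
    "latent_recovery",
    "linear_construct_r",
    "duplicate_construct_r",
    "control_nonsignificant_fraction",
    "trending_significance_rate",
]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent 31-bit integer seeds from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Oracle equivalence

def oracle_deviations(seed: int = 0, n_instances: int = 100) -> dict[str, float]:
    """Max absolute deviation of pearson / zscore / rolling_mean from the
    brute-force references over random instances."""
    rng = np.random.default_rng(seed)
    dev = {"pearson_r": 0.0, "pearson_p": 0.0, "zscore": 0.0, "rolling_mean": 0.0}
    for _ in range(n_instances):
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n) * rng.uniform(0.5, 20)
        y = rng.normal(size=n) + rng.uniform(-0.9, 0.9) * x
        res = pearson(x, y)
        r_ref, p_ref = bf.pearson_reference(x, y)
        dev["pearson_r"] = max(dev["pearson_r"], abs(res.r - r_ref))
        dev["pearson_p"] = max(dev["pearson_p"], abs(res.p - p_ref))
        z = zscore_series(x)
        z_ref = np.asarray(bf.zscore_reference(x))
        dev["zscore"] = max(dev["zscore"], float(np.abs(z - z_ref).max()))
        w = int(rng.integers(1, n + 1))
        roll = rolling_mean(np.abs(x), window=w)
        roll_ref = np.asarray(bf.rolling_mean_reference(np.abs(x), w))
        dev["rolling_mean"] = max(
            dev["rolling_mean"], float(np.abs(roll.values - roll_ref).max())
        )
    return dev


# ---------------------------------------------------------------------------
# Influx invariance and aggregation insensitivity

def _small_truth(seed: int, **kw) -> SyntheticTruth:
    defaults = dict(
        seed=int(seed),
        n_years=50,
        languages=("en-GB-2019",),
        constructs={
            "a": ConstructSpec(8, trend_slope=0.01, latent_loading=0.5),
            "b": ConstructSpec(8, trend_slope=0.0, latent_loading=0.5),
        },
        noise_sd=0.15,
    )
    defaults.update(kw)
    return SyntheticTruth(**defaults)


def influx_invariance_max_diff(seed: int = 0, n_panels: int = 20) -> float:
    """Max cell-wise change in an adjusted composite after applying random
    year-wise inflation.  Should be ~1e-15; the acceptance bound is 1e-9."""
    worst = 0.0
    for s in _spawn_seeds(seed, n_panels):
        ds = generate_panel(_small_truth(int(s)))
        panel = ds.panels["en-GB-2019"]
        rng = np.random.default_rng(int(s) + 1)
        factors = {int(y): float(f) for y, f in
                   zip(panel.years, rng.uniform(0.2, 5.0, len(panel.years)))}
        cw = ds.truth.common_word
        words = [w for w in panel.words if w != cw]
        base = composite(common_word_adjust(panel, cw), words, construct="all")
        inflated = composite(
            common_word_adjust(inflate_panel(panel, factors), cw),
            words, construct="all",
        )
        worst = max(worst, float(np.abs(base.values - inflated.values).max()))
    return worst


def aggregation_max_r_diff(seed: int = 0, n_panels: int = 20) -> float:
    """Max |r_mean - r_sum| over all correlation-matrix cells when the word
    aggregation switches between mean and sum."""
    worst = 0.0
    for s in _spawn_seeds(seed, n_panels):
        ds = generate_panel(_small_truth(int(s)))
        panel = ds.panels["en-GB-2019"]
        adjusted = common_word_adjust(panel, ds.truth.common_word)
        words = {
            c: [w for w, cc in ds.word_constructs.items() if cc == c]
            for c in ds.truth.constructs
        }
        for agg_pair in [("mean", "sum")]:
            comps = {
                agg: [
                    composite(adjusted, words[c], construct=c, aggregation=agg)
                    for c in words
                ]
                for agg in agg_pair
            }
            m_mean = correlation_matrix(comps["mean"])
            m_sum = correlation_matrix(comps["sum"])
            for key, res in m_mean.results.items():
                worst = max(worst, abs(res.r - m_sum.results[key].r))
    return worst


# ---------------------------------------------------------------------------
# Null calibration and recovery

def _two_construct_rs(
    n_reps: int,
    seed: int,
    n_words: int,
    n_years: int,
    noise_sd: float,
    loading: float,
    trend_slope: float = 0.0,
    latent: str = "iid",
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full pipeline (generate -> adjust -> composite -> pearson) on
    replicate panels of two constructs; return arrays of r and p."""
    rs = np.empty(n_reps)
    ps = np.empty(n_reps)
    spec = ConstructSpec(n_words, trend_slope=trend_slope, latent_loading=loading)
    for k, s in enumerate(_spawn_seeds(seed, n_reps)):
        truth = SyntheticTruth(
            seed=int(s),
            n_years=n_years,
            languages=("en-GB-2019",),
            constructs={"a": spec, "b": spec},
            noise_sd=noise_sd,
            latent=latent,
            base_log_mean=math.log(1e-3),
        )
        ds = generate_panel(truth)
        adjusted = common_word_adjust(ds.panels["en-GB-2019"], truth.common_word)
        comp = {
            c: composite(
                adjusted,
                [w for w, cc in ds.word_constructs.items() if cc == c],
                construct=c,
            )
            for c in ("a", "b")
        }
        res = pearson(comp["a"].values, comp["b"].values, pair=("a", "b"))
        rs[k], ps[k] = res.r, res.p
    return rs, ps


def type1_error_rate(
    n_reps: int = 10_000,
    seed: int = 0,
    n_words: int = 10,
    n_years: int = 50,
    noise_sd: float = 0.15,
) -> float:
    """Fraction of construct-pair tests with p < .05 under the independent
    null: zero slopes, zero latent loading, iid year noise."""
    _, ps = _two_construct_rs(
        n_reps, seed, n_words, n_years, noise_sd, loading=0.0, latent="iid"
    )
    return float((ps < 0.05).mean())


def latent_recovery(
    seed: int = 0,
    n_reps_pipeline: int = 200,
    n_reps_oracle: int = 2000,
    n_words: int = 10,
    n_years: int = 50,
    noise_sd: float = 0.5,
    loading: float = math.sqrt(0.1),
) -> dict[str, float]:
    """Mean composite-composite r from the pipeline vs. the brute-force
    Monte-Carlo oracle of the generative formula.

    With iid latent, population r is loading^2 / (loading^2 + noise_sd^2 /
    n_words) up to the log-normal curvature — ~0.8 at the defaults.
    """
    rs, _ = _two_construct_rs(
        n_reps_pipeline, seed, n_words, n_years, noise_sd, loading, latent="iid"
    )
    oracle = bf.direct_composite_correlation(
        n_reps_oracle, seed + 1, n_words=n_words, n_years=n_years,
        noise_sd=noise_sd, loading=loading,
    )
    return {
        "pipeline_mean_r": float(rs.mean()),
        "oracle_mean_r": oracle,
        "abs_gap": abs(float(rs.mean()) - oracle),
    }


# ---------------------------------------------------------------------------
# Degenerate fidelity

def linear_construct_r(n_years: int = 50, year_start: int = 1970) -> float:
    """r between years and a composite built from words whose adjusted
    frequencies are exactly linear in the year.  Must be 1 to rounding."""
    years = np.arange(year_start, year_start + n_years)
    t = np.arange(n_years, dtype=float)
    cols = {f"w{j}": 0.5 + (0.01 + 0.005 * j) * t for j in range(5)}
    cols["corpusmax"] = np.full(n_years, 10.0)
    panel = FrequencyPanel(
        "en-GB-2019", pd.DataFrame(cols, index=pd.Index(years, name="year"))
    )
    comp = composite(
        common_word_adjust(panel, "corpusmax"),
        [f"w{j}" for j in range(5)],
        construct="linear",
    )
    return pearson(comp.values, years.astype(float), pair=("linear", "Years")).r


def duplicate_construct_r(seed: int = 0) -> float:
    """Off-diagonal r between a construct and an exact copy of its list."""
    ds = generate_panel(_small_truth(seed))
    panel = ds.panels["en-GB-2019"]
    adjusted = common_word_adjust(panel, ds.truth.common_word)
    words_a = [w for w, c in ds.word_constructs.items() if c == "a"]
    ca = composite(adjusted, words_a, construct="a")
    cb = composite(adjusted, words_a, construct="a_copy")
    return correlation_matrix([ca, cb]).get("a", "a_copy").r


def control_nonsignificant_fraction(
    n_reps: int = 1000,
    seed: int = 0,
    n_words: int = 10,
    n_years: int = 50,
    noise_sd: float = 0.15,
) -> float:
    """Fraction of replicates in which a zero-loading, zero-slope control
    construct is NOT significantly correlated (p >= .05) with a trending,
    latent-loaded study construct."""
    frac_sig = 0
    signal = ConstructSpec(n_words, trend_slope=0.02, latent_loading=0.8)
    control = ConstructSpec(n_words, trend_slope=0.0, latent_loading=0.0)
    for s in _spawn_seeds(seed, n_reps):
        truth = SyntheticTruth(
            seed=int(s),
            n_years=n_years,
            languages=("en-GB-2019",),
            constructs={"signal": signal, "control": control},
            noise_sd=noise_sd,
            latent="walk",
        )
        ds = generate_panel(truth)
        adjusted = common_word_adjust(ds.panels["en-GB-2019"], truth.common_word)
        comp = {
            c: composite(
                adjusted,
                [w for w, cc in ds.word_constructs.items() if cc == c],
                construct=c,
            )
            for c in ("signal", "control")
        }
        res = pearson(comp["signal"].values, comp["control"].values)
        frac_sig += res.p < 0.05
    return 1.0 - frac_sig / n_reps


def trending_significance_rate(
    n_reps: int = 300,
    seed: int = 0,
    n_words: int = 10,
    n_years: int = 50,
    noise_sd: float = 0.15,
    trend_slope: float = 0.02,
) -> float:
    """Rejection rate for two constructs with equal deterministic trends but
    independent noise — the classic spurious-correlation caveat for
    non-stationary series.  Far exceeds the nominal 5%."""
    _, ps = _two_construct_rs(
        n_reps, seed, n_words, n_years, noise_sd,
        loading=0.0, trend_slope=trend_slope, latent="iid",
    )
    return float((ps < 0.05).mean())
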