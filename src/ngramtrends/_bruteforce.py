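"""Naive reference implementations used as independent cross-checks.

Everything here is written from the defining formulas with explicit loops
or direct Monte-Carlo simulation of the generative model, deliberately
sharing no code with the optimized implementations it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import stdtr


def pearson_reference(x, y) -> tuple[float, float]:
    """Pearson r from the explicit sums formula; two-sided p from the t CDF."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    r = num / den
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stdtr(n - 2, -abs(t))
    return r, p


def zscore_reference(values) -> list[float]:
    """Two-pass standardization with the sample (n-1) standard deviation."""
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    var = sum((v - mean) ** 2 for v in xs) / (n - 1)
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in xs]


def rolling_mean_reference(values, window: int) -> list[float]:
    """Per-window arithmetic mean by an explicit loop."""
    xs = [float(v) for v in values]
    out = []
    for i in range(window - 1, len(xs)):
        out.append(sum(xs[i - window + 1: i + 1]) / window)
    return out


def direct_composite_correlation(
    n_reps: int,
    seed: int,
    n_words: int = 10,
    n_years: int = 50,
    noise_sd: float = 0.5,
    loading: float = math.sqrt(0.1),
    base_log_mean: float = math.log(1e-3),
    base_log_sd: float = 0.5,
) -> float:
    """Mean sample correlation of two composites, simulated from the formula.

    Directly simulates adjusted word series exp(alpha_w + loading*L(t) +
    eps) for two constructs sharing an iid standard-Gaussian latent path
    (the year-wise inflation and the constant common-word level divide out
    of the adjusted ratio and drop out of the z-transform), z-scores each
    word, averages, and correlates — all in plain numpy, no pipeline code.
    """
    rng = np.random.default_rng(seed)
    rs = np.empty(n_reps)
    for k in range(n_reps):
        latent = rng.standard_normal(n_years)
        comps = []
        for _ in range(2):
            alphas = rng.normal(base_log_mean, base_log_sd, n_words)
            eps = rng.normal(0.0, noise_sd, (n_years, n_words))
            series = np.exp(alphas[None, :] + loading * latent[:, None] + eps)
            z = (series - series.mean(axis=0)) / series.std(axis=0, ddof=1)
            comps.append(z.mean(axis=1))
        a, b = comps
        rs[k] = np.corrcoef(a, b)[0, 1]
    return float(rs.mean())
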