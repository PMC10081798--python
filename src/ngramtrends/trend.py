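"""Trend statistics: Pearson correlation matrices and rolling-mean diagnostics.

Correlations are plain sample Pearson r with two-sided p-values from the
exact t transform, t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
Significance stars follow the conventional thresholds (* p<.05, ** p<.01,
*** p<.001); a Holm-adjusted p-value is carried alongside each cell for
transparency but does not drive the stars, matching the per-cell convention
of correlation tables in this literature.

Rolling means over five consecutive years serve as a qualitative
non-stationarity diagnostic: a word whose windowed mean keeps climbing is a
trending (non-stationary) series, and correlations between trending series
are easily spurious.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import CompositeSeries

__all__ = [
    "CorrelationResult",
    "CorrelationMatrix",
    "RollingSeries",
    "TrendError",
    "stars_for",
    "pearson",
    "correlation_matrix",
    "rolling_mean",
    "trend_label",
]

YEAR_LABEL = "Years"


class TrendError(ValueError):
    """Invalid input to a trend statistic."""


def stars_for(p: float) -> str:
    """Significance stars at the .05 / .01 / .001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    stars: str
    holm_p: float | None = None


def pearson(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Both series need length n >= 3 and positive variance; r is clamped to
    [-1, 1] against floating-point overshoot.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise TrendError(f"{pair}: series shapes differ ({xa.shape} vs {ya.shape})")
    n = xa.size
    if n < 3:
        raise TrendError(f"{pair}: need n >= 3, got {n}")
    if xa.std(ddof=1) == 0 or ya.std(ddof=1) == 0:
        raise TrendError(f"{pair}: zero variance")
    res = stats.pearsonr(xa, ya)
    r = float(min(1.0, max(-1.0, res.statistic)))
    p = float(res.pvalue)
    return CorrelationResult(pair=pair, r=r, p=p, n=n, stars=stars_for(p))


@dataclass
class CorrelationMatrix:
    """Lower-triangular pairwise correlations among construct composites,
    the calendar-year index, and the control construct (ordered last)."""

    language: str
    labels: list[str]
    results: dict[tuple[str, str], CorrelationResult] = field(default_factory=dict)
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    def get(self, a: str, b: str) -> CorrelationResult:
        key = (a, b) if (a, b) in self.results else (b, a)
        return self.results[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), res in self.results.items():
            rows.append(
                {
                    "pair_a": a,
                    "pair_b": b,
                    "language": self.language,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "stars": res.stars,
                    "holm_p": res.holm_p,
                }
            )
        for (a, b), msg in self.errors.items():
            rows.append(
                {
                    "pair_a": a,
                    "pair_b": b,
                    "language": self.language,
                    "r": np.nan,
                    "p": np.nan,
                    "n": 0,
                    "stars": "",
                    "holm_p": np.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["pair_a", "pair_b", "language", "r", "p", "n", "stars", "holm_p"],
        )

    def to_text(self) -> str:
        """Lower-triangular display with significance stars."""
        width = max(len(l) for l in self.labels) + 3
        lines = [" " * width + "".join(f"{i + 1:>10d}" for i in range(len(self.labels) - 1))]
        for i, row_label in enumerate(self.labels):
            cells = []
            for j in range(i):
                key = (row_label, self.labels[j])
                key = key if key in self.results else (self.labels[j], row_label)
                if key in self.results:
                    res = self.results[key]
                    cells.append(f"{res.r:+.2f}{res.stars:<3s}".rjust(10))
                else:
                    cells.append("--".rjust(10))
            lines.append(f"{i + 1} {row_label}".ljust(width) + "".join(cells))
        lines.append("Note. * p < .05; ** p < .01; *** p < .001.")
        return "\n".join(lines)


def correlation_matrix(
    composites: Sequence[CompositeSeries],
    year_index: Sequence[float] | None = None,
    control_construct: str | None = None,
) -> CorrelationMatrix:
    """All pairwise correlations among construct composites and calendar years.

    Row order mirrors the conventional table layout: study constructs in the
    given order, then the year index, then the control construct.  Cells
    whose correlation cannot be computed (zero variance, short series) are
    recorded as errors rather than aborting the matrix.  Holm-adjusted
    p-values over all computed cells are attached for transparency.
    """
    if not composites:
        raise TrendError("no composites given")
    first = composites[0]
    for c in composites:
        if not np.array_equal(c.years, first.years):
            raise TrendError(f"{c.construct}/{c.language}: mismatched year range")
    language = first.language
    series: dict[str, np.ndarray] = {}
    order: list[str] = []
    control: str | None = None
    for c in composites:
        if c.construct in series:
            raise TrendError(f"duplicate construct {c.construct!r}")
        series[c.construct] = np.asarray(c.values, dtype=float)
        if control_construct is not None and c.construct == control_construct:
            control = c.construct
        else:
            order.append(c.construct)
    years = np.asarray(year_index if year_index is not None else first.years, float)
    if years.size != len(first.years):
        raise TrendError("year_index length mismatch")
    series[YEAR_LABEL] = years
    order.append(YEAR_LABEL)
    if control_construct is not None:
        if control is None:
            raise TrendError(f"control construct {control_construct!r} not supplied")
        order.append(control)

    matrix = CorrelationMatrix(language=language, labels=order)
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            try:
                matrix.results[(a, b)] = pearson(series[a], series[b], pair=(a, b))
            except TrendError as exc:
                matrix.errors[(a, b)] = str(exc)
    if matrix.results:
        keys = list(matrix.results)
        holm = multipletests([matrix.results[k].p for k in keys], method="holm")[1]
        for k, hp in zip(keys, holm):
            matrix.results[k] = replace(matrix.results[k], holm_p=float(hp))
    return matrix


@dataclass(frozen=True)
class RollingSeries:
    """Windowed means of one word's raw frequency series."""

    word: str
    language: str
    construct: str
    window: int
    years: np.ndarray
    values: np.ndarray


def rolling_mean(
    series,
    window: int = 5,
    years: Sequence[int] | None = None,
    word: str = "",
    language: str = "",
    construct: str = "",
    center: bool = False,
) -> RollingSeries:
    """Mean of each run of ``window`` consecutive values (default five years).

    Windows are trailing by default (value at position i averages positions
    i-window+1 .. i), keeping the diagnostic causal; ``center=True`` shifts
    the year labels to the window midpoint instead.  Output length is
    n - window + 1.
    """
    if isinstance(series, pd.Series):
        if years is None:
            years = series.index.to_numpy()
        series = series.to_numpy()
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise TrendError("window must be >= 1")
    if x.size < window:
        raise TrendError(f"series length {x.size} shorter than window {window}")
    values = np.convolve(x, np.full(window, 1.0 / window), mode="valid")
    if years is None:
        years = np.arange(x.size)
    years = np.asarray(years, dtype=int)
    if years.size != x.size:
        raise TrendError("years/series length mismatch")
    labels = years[window - 1:]
    if center:
        labels = labels - window // 2
    return RollingSeries(
        word=word, language=language, construct=construct,
        window=window, years=labels, values=values,
    )


def trend_label(rolling: RollingSeries, slope_epsilon: float | None = None) -> str:
    """Classify a rolling-mean series as increase / decrease / flat.

    The OLS slope of the windowed means on window position is compared
    against ``slope_epsilon`` (default: 1% of the series' value range per
    step); the inequalities are strict, so a slope exactly at the threshold
    is flat.
    """
    v = np.asarray(rolling.values, dtype=float)
    if v.size < 2:
        raise TrendError("need at least two rolling values")
    if v.max() == v.min():
        return "flat"
    if slope_epsilon is None:
        slope_epsilon = 0.01 * (v.max() - v.min())
    slope = float(np.polyfit(np.arange(v.size), v, 1)[0])
    if slope > slope_epsilon:
        return "increase"
    if slope < -slope_epsilon:
        return "decrease"
    return "flat"
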