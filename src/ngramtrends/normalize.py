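"""Composite construct indices: common-word adjustment, z-scores, pooling.

The normalization chain turns a raw frequency panel plus a lexicon into a
per-language composite index:

1. **most-common-word adjustment** — divide every word's series by the
   corpus's most frequent word (noun) in the same year.  Year-wise corpus
   "influx" multipliers hit numerator and denominator alike, so the ratio
   cancels them exactly;
2. **z-transformation** — each adjusted word series is standardized over
   the year range (sample sd, n-1);
3. **aggregation** — the per-year mean (or sum) over the list's surviving
   words.  Pearson correlations downstream are identical under either
   aggregation since r is scale-invariant.

Cross-language pooling averages the per-language composites year by year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, filtered_words
from .ngram_io import FrequencyPanel

__all__ = [
    "CompositeSeries",
    "NormalizeError",
    "ZeroVarianceError",
    "common_word_adjust",
    "zscore_series",
    "composite",
    "pool_languages",
]

log = logging.getLogger(__name__)

POOLED = "pooled"


class NormalizeError(ValueError):
    """Invalid input to the normalization chain."""


class ZeroVarianceError(NormalizeError):
    """A series is constant and cannot be z-transformed."""


@dataclass(frozen=True)
class CompositeSeries:
    """Yearly composite index for one construct in one language (or pooled).

    Values are unitless (z-scale).  Single-language composites average
    zero-mean word z-series, so their mean over years is 0 to rounding.
    """

    construct: str
    language: str
    years: np.ndarray
    values: np.ndarray
    n_words: int
    n_languages: int = 1
    dropped_words: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise NormalizeError("years/values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"),
                         name=f"{self.construct}/{self.language}")

    def __len__(self) -> int:
        return len(self.values)


def common_word_adjust(panel: FrequencyPanel, common_word: str) -> FrequencyPanel:
    """Divide every word's series by the most-common word's, dropping it.

    The output is a panel of unitless ratios; any year where the common
    word's frequency is not strictly positive is an error (the adjustment
    would divide by zero).
    """
    if common_word not in panel.data.columns:
        raise NormalizeError(
            f"{panel.language}: common word {common_word!r} not in panel"
        )
    denom = panel.data[common_word]
    bad = denom.index[denom.to_numpy() <= 0]
    if len(bad):
        raise NormalizeError(
            f"{panel.language}: common word {common_word!r} has non-positive "
            f"frequency in year {int(bad[0])}"
        )
    adjusted = panel.data.drop(columns=[common_word]).div(denom, axis=0)
    obs = None
    if panel.observed is not None:
        obs = panel.observed.drop(columns=[common_word])
    return FrequencyPanel(language=panel.language, data=adjusted, observed=obs)


def zscore_series(values) -> np.ndarray:
    """Standardize a series: (x - mean) / sample sd (ddof=1).

    Raises :class:`ZeroVarianceError` for constant input; callers may drop
    and log such words.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise NormalizeError("zscore_series needs a 1-d series of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("constant series has no z-transform")
    return (x - x.mean()) / sd


def composite(
    adjusted: FrequencyPanel,
    lexicon: Lexicon | Sequence[str],
    construct: str | None = None,
    aggregation: str = "mean",
    zero_variance_policy: str = "drop",
) -> CompositeSeries:
    """Aggregate the z-scored adjusted series of a word list into one index.

    ``lexicon`` may be a :class:`Lexicon` (its included words are used) or a
    plain word sequence.  Zero-variance words are dropped with a warning
    under the default policy (``fail`` raises instead); at least one word
    must survive.
    """
    if isinstance(lexicon, Lexicon):
        words = filtered_words(lexicon)
        construct = construct or lexicon.construct
    else:
        words = list(lexicon)
        if construct is None:
            raise NormalizeError("construct label required for a plain word list")
    if aggregation not in ("mean", "sum"):
        raise NormalizeError(f"unknown aggregation {aggregation!r}")
    if zero_variance_policy not in ("drop", "fail"):
        raise NormalizeError(f"unknown zero_variance_policy {zero_variance_policy!r}")
    missing = [w for w in words if w not in adjusted.data.columns]
    if missing:
        raise NormalizeError(
            f"{construct}/{adjusted.language}: words missing from panel: {missing}"
        )
    block = adjusted.data[words].to_numpy(dtype=float)
    sds = block.std(axis=0, ddof=1)
    flat = sds == 0
    if flat.any():
        flat_words = [w for w, f in zip(words, flat) if f]
        if zero_variance_policy == "fail":
            raise ZeroVarianceError(
                f"{construct}/{adjusted.language}: constant series for {flat_words}"
            )
        log.warning(
            "%s/%s: dropping %d zero-variance word(s): %s",
            construct, adjusted.language, len(flat_words), flat_words,
        )
    keep = ~flat
    if not keep.any():
        raise NormalizeError(
            f"{construct}/{adjusted.language}: no words with positive variance"
        )
    z = (block[:, keep] - block[:, keep].mean(axis=0)) / sds[keep]
    values = z.sum(axis=1) if aggregation == "sum" else z.mean(axis=1)
    return CompositeSeries(
        construct=construct,
        language=adjusted.language,
        years=adjusted.years.copy(),
        values=values,
        n_words=int(keep.sum()),
        dropped_words=tuple(w for w, f in zip(words, flat) if f),
    )


def pool_languages(
    series: Sequence[CompositeSeries], construct: str | None = None
) -> CompositeSeries:
    """Average per-language composites into one cross-language index.

    All inputs must share construct and year range.  Pooling is an
    unweighted mean over languages; ``n_words`` records the summed
    surviving-word count.
    """
    if not series:
        raise NormalizeError("pool_languages needs at least one composite")
    first = series[0]
    construct = construct or first.construct
    for s in series:
        if s.construct != construct:
            raise NormalizeError(
                f"mixed constructs: {s.construct!r} vs {construct!r}"
            )
        if not np.array_equal(s.years, first.years):
            raise NormalizeError(f"mismatched year ranges for {s.language}")
    stacked = np.column_stack([s.values for s in series])
    return CompositeSeries(
        construct=construct,
        language=POOLED,
        years=first.years.copy(),
        values=stacked.mean(axis=1),
        n_words=int(sum(s.n_words for s in series)),
        n_languages=len(series),
    )
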