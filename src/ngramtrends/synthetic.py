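"""Synthetic multi-language ngram panels with known ground truth.

The generator emulates the data model of a books-corpus frequency study:
each word's yearly relative frequency is log-normal,

    f(w, t) = inflation(t) * exp(alpha_w + slope_c * t + lambda_c * L(t) + eps_{w,t})

where ``c`` is the word's construct, ``L(t)`` is a latent path shared by all
constructs with nonzero loading (a Gaussian random walk rescaled to unit
sample variance by default, or iid Gaussian for clean null experiments),
``eps`` is iid Gaussian noise, and ``inflation(t)`` is a year-wise corpus
"influx" multiplier applied to every word.  A designated most-common word is
generated at a level dominating every other series in every year, so the
most-common-word adjustment downstream can cancel the inflation exactly.

Log-normal construction guarantees positivity, and slopes act on the log
scale so rising word use is multiplicative — the visual character of real
ngram curves.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ngram_io import FrequencyPanel

__all__ = [
    "ConstructSpec",
    "SyntheticTruth",
    "SyntheticDataset",
    "SyntheticError",
    "default_constructs",
    "generate_panel",
    "inflate_panel",
]

DEFAULT_LANGUAGES = (
    "en-GB-2019",
    "de-2019",
    "es-2019",
    "ru-2019",
    "fr-2019",
    "it-2019",
)

#: Name given to the generated most-common-word series in every panel.
COMMON_WORD = "corpusmax"


class SyntheticError(ValueError):
    """Invalid generator parameters or a violated construction guarantee."""


@dataclass(frozen=True)
class ConstructSpec:
    """Per-construct generator parameters.

    trend_slope is per-year on the log scale; latent_loading in [0, 1]
    couples the construct to the shared latent path.
    """

    n_words: int
    trend_slope: float = 0.0
    latent_loading: float = 0.0

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise SyntheticError("n_words must be >= 1")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise SyntheticError("latent_loading must lie in [0, 1]")


def default_constructs() -> dict[str, ConstructSpec]:
    """Word counts follow the published final lists (26 anxiety/depression
    words split evenly, 33 digitalization words, 19 religion control words);
    the three study constructs rise and share a latent path, the control
    does neither."""
    return {
        "anxiety": ConstructSpec(13, trend_slope=0.02, latent_loading=0.8),
        "depression": ConstructSpec(13, trend_slope=0.02, latent_loading=0.8),
        "digitalization": ConstructSpec(33, trend_slope=0.03, latent_loading=0.8),
        "religion": ConstructSpec(19, trend_slope=0.0, latent_loading=0.0),
    }


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one synthetic dataset (for recovery tests)."""

    seed: int = 0
    n_years: int = 50
    year_start: int = 1970
    languages: tuple[str, ...] = DEFAULT_LANGUAGES
    constructs: Mapping[str, ConstructSpec] = field(default_factory=default_constructs)
    noise_sd: float = 0.15
    #: year -> multiplier; None means exp(inflation_growth * t)
    inflation: Mapping[int, float] | None = None
    inflation_growth: float = 0.03
    common_word: str = COMMON_WORD
    common_word_level: float = 5.0
    common_word_noise_sd: float = 0.0
    #: 'walk' = unit-variance Gaussian random walk (realistic autocorrelation),
    #: 'iid' = independent Gaussian years (clean type-I-error experiments)
    latent: str = "walk"
    base_log_mean: float = math.log(1e-3)
    base_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise SyntheticError("n_years must be >= 2")
        if self.noise_sd <= 0:
            raise SyntheticError("noise_sd must be > 0")
        if self.common_word_level <= 0:
            raise SyntheticError("common_word_level must be > 0")
        if self.latent not in ("walk", "iid"):
            raise SyntheticError(f"unknown latent mode {self.latent!r}")
        if not self.languages:
            raise SyntheticError("at least one language required")
        if not self.constructs:
            raise SyntheticError("at least one construct required")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_start + self.n_years)

    def inflation_factors(self) -> np.ndarray:
        t = np.arange(self.n_years, dtype=float)
        if self.inflation is None:
            return np.exp(self.inflation_growth * t)
        factors = np.array([self.inflation[int(y)] for y in self.years], dtype=float)
        if (factors <= 0).any():
            raise SyntheticError("inflation factors must be positive")
        return factors

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constructs"] = {k: dataclasses.asdict(v) for k, v in self.constructs.items()}
        d["languages"] = list(self.languages)
        if self.inflation is not None:
            d["inflation"] = {int(k): float(v) for k, v in self.inflation.items()}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True),
                              encoding="utf-8")


@dataclass
class SyntheticDataset:
    panels: dict[str, FrequencyPanel]
    truth: SyntheticTruth
    latent_path: np.ndarray
    #: word -> construct, identical across languages
    word_constructs: dict[str, str]


def _latent_path(rng: np.random.Generator, n_years: int, mode: str) -> np.ndarray:
    g = rng.standard_normal(n_years)
    if mode == "iid":
        return g
    walk = np.cumsum(g)
    sd = walk.std(ddof=1)
    if sd == 0:  # pragma: no cover - measure-zero event
        return walk - walk.mean()
    return (walk - walk.mean()) / sd


def generate_panel(truth: SyntheticTruth) -> SyntheticDataset:
    """Generate one :class:`FrequencyPanel` per language from ``truth``.

    The latent path is drawn once and shared across languages and constructs;
    baselines and noise are independent per language.  Fully reproducible
    from ``truth.seed``.  Raises if the common word fails to dominate every
    other series in any year (a post-hoc guarantee check).
    """
    ss = np.random.SeedSequence(truth.seed)
    latent_ss, *lang_ss = ss.spawn(1 + len(truth.languages))
    latent = _latent_path(np.random.default_rng(latent_ss), truth.n_years, truth.latent)

    t = np.arange(truth.n_years, dtype=float)
    inflation = truth.inflation_factors()
    years = pd.Index(truth.years, name="year")

    word_constructs: dict[str, str] = {}
    for cname, spec in truth.constructs.items():
        for i in range(spec.n_words):
            word_constructs[f"{cname}_w{i:02d}"] = cname

    panels: dict[str, FrequencyPanel] = {}
    for language, child in zip(truth.languages, lang_ss):
        rng = np.random.default_rng(child)
        columns: dict[str, np.ndarray] = {}
        for cname, spec in truth.constructs.items():
            alphas = rng.normal(truth.base_log_mean, truth.base_log_sd, spec.n_words)
            eps = rng.normal(0.0, truth.noise_sd, (truth.n_years, spec.n_words))
            logf = (
                alphas[None, :]
                + spec.trend_slope * t[:, None]
                + spec.latent_loading * latent[:, None]
                + eps
            )
            freq = inflation[:, None] * np.exp(logf)
            for i in range(spec.n_words):
                columns[f"{cname}_w{i:02d}"] = freq[:, i]
        cw_noise = rng.normal(0.0, 1.0, truth.n_years) * truth.common_word_noise_sd
        common = inflation * truth.common_word_level * np.exp(cw_noise)
        word_max = np.max(np.column_stack(list(columns.values())), axis=1)
        if not (common > word_max).all():
            bad = int(truth.years[np.argmax(word_max >= common)])
            raise SyntheticError(
                f"{language}: common word not dominant in year {bad}; "
                "raise common_word_level or lower word baselines"
            )
        columns[truth.common_word] = common
        data = pd.DataFrame(columns, index=years)
        panels[language] = FrequencyPanel(language=language, data=data)
    return SyntheticDataset(
        panels=panels, truth=truth, latent_path=latent, word_constructs=word_constructs
    )


def inflate_panel(
    panel: FrequencyPanel, factors: Mapping[int, float]
) -> FrequencyPanel:
    """Multiply every cell (common word included) by its year's factor."""
    try:
        mult = np.array([factors[int(y)] for y in panel.years], dtype=float)
    except KeyError as exc:
        raise SyntheticError(f"inflation factor missing for year {exc}") from None
    if (mult <= 0).any():
        raise SyntheticError("inflation factors must be positive")
    data = panel.data.mul(mult, axis=0)
    obs = panel.observed.copy() if panel.observed is not None else None
    return FrequencyPanel(language=panel.language, data=data, observed=obs)
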