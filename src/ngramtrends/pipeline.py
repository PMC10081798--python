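"""Run configuration and end-to-end orchestration.

One config drives the whole run: which corpora, which year range, where the
word lists live, which data source feeds the panels (synthetic generator,
Viewer JSON exports, raw ngram files, or a query cache), and the
normalization choices.  ``run_pipeline`` executes

    lexicon -> panels -> adjust/z/aggregate -> correlations + rolling means

and writes CSV artifacts plus a manifest (config hash, seed, version) that
make the run reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lexicon import Lexicon, load_lexicon
from .ngram_io import (
    FrequencyPanel,
    fetch_panel,
    parse_raw_ngram,
    parse_totalcounts,
    parse_viewer_json,
    read_panel_csv,
)
from .normalize import CompositeSeries, common_word_adjust, composite, pool_languages
from .synthetic import ConstructSpec, SyntheticTruth, default_constructs, generate_panel
from .trend import CorrelationMatrix, correlation_matrix, rolling_mean, trend_label

__all__ = [
    "RunConfig",
    "RunReport",
    "ConfigError",
    "KNOWN_CORPORA",
    "validate_config",
    "run_pipeline",
]

log = logging.getLogger(__name__)

#: 2019-release corpus labels for the six study languages plus English fiction.
KNOWN_CORPORA = frozenset(
    {
        "en-GB-2019",
        "de-2019",
        "es-2019",
        "ru-2019",
        "fr-2019",
        "it-2019",
        "en-fiction-2019",
    }
)

DATA_SOURCES = ("synthetic", "viewer_json", "raw_tsv", "cache")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    corpora: list[str] = field(default_factory=lambda: sorted(KNOWN_CORPORA - {"en-fiction-2019"}))
    year_start: int = 1970
    year_end: int = 2019
    data_source: str = "synthetic"
    seed: int = 0
    #: construct -> {corpus label -> word-list TSV path}; may be empty for
    #: the synthetic source (lists then come from the generator).
    constructs: dict[str, dict[str, str]] = field(default_factory=dict)
    control_construct: str | None = "religion"
    #: corpus label -> most frequent noun used for the influx adjustment.
    common_word: dict[str, str] = field(default_factory=dict)
    aggregation: str = "mean"
    zero_variance_policy: str = "drop"
    smoothing: int = 0
    rolling_window: int = 5
    #: overrides for SyntheticTruth fields (synthetic source only).
    synthetic: dict = field(default_factory=dict)
    panel_dir: str | None = None
    cache_dir: str | None = None
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration problems (empty list = valid).  Pure."""
    problems: list[str] = []
    if config.year_end < config.year_start + 2:
        problems.append(
            f"year range {config.year_start}..{config.year_end} too short "
            "(need at least 3 years)"
        )
    for corpus in config.corpora:
        if corpus not in KNOWN_CORPORA:
            problems.append(f"unknown corpus label {corpus!r}")
    if not config.corpora:
        problems.append("no corpora configured")
    if config.data_source not in DATA_SOURCES:
        problems.append(f"unknown data_source {config.data_source!r}")
    if config.aggregation not in ("mean", "sum"):
        problems.append(f"unknown aggregation {config.aggregation!r}")
    if config.zero_variance_policy not in ("drop", "fail"):
        problems.append(f"unknown zero_variance_policy {config.zero_variance_policy!r}")
    if config.rolling_window < 1:
        problems.append("rolling_window must be >= 1")
    if config.data_source != "synthetic":
        if not config.constructs:
            problems.append("no construct word lists configured")
        for construct, paths in config.constructs.items():
            for corpus in config.corpora:
                p = paths.get(corpus)
                if p is None:
                    problems.append(f"{construct}: no word list for {corpus}")
                elif not Path(p).exists():
                    problems.append(f"{construct}/{corpus}: word list {p} not found")
        for corpus in config.corpora:
            if corpus not in config.common_word:
                problems.append(f"no common_word configured for {corpus}")
        if config.control_construct and config.control_construct not in config.constructs:
            problems.append(
                f"control construct {config.control_construct!r} has no word lists"
            )
        if config.data_source in ("viewer_json", "raw_tsv") and not config.panel_dir:
            problems.append(f"data_source {config.data_source} requires panel_dir")
        if config.data_source == "cache" and not config.cache_dir:
            problems.append("data_source cache requires cache_dir")
    return problems


@dataclass
class RunReport:
    paths: dict[str, str]
    manifest: dict
    composites: list[CompositeSeries]
    matrices: dict[str, CorrelationMatrix]


def _truth_from_config(config: RunConfig) -> SyntheticTruth:
    overrides = dict(config.synthetic)
    raw_constructs = overrides.pop("constructs", None)
    if raw_constructs is None:
        constructs = default_constructs()
    else:
        constructs = {
            name: ConstructSpec(**spec) for name, spec in raw_constructs.items()
        }
    n_years = config.year_end - config.year_start + 1
    return SyntheticTruth(
        seed=config.seed,
        n_years=n_years,
        year_start=config.year_start,
        languages=tuple(config.corpora),
        constructs=constructs,
        **overrides,
    )


def build_panels(
    config: RunConfig, lexicons: Mapping[tuple[str, str], Lexicon] | None = None
) -> tuple[dict[str, FrequencyPanel], dict[str, list[str]], SyntheticTruth | None]:
    """Assemble per-corpus panels plus construct word lists per corpus.

    Returns (panels, construct word map keyed ``construct``, truth-or-None).
    For file-backed sources the word map is per-corpus via the lexicons.
    """
    if config.data_source == "synthetic":
        truth = _truth_from_config(config)
        ds = generate_panel(truth)
        words = {
            c: [w for w, cc in ds.word_constructs.items() if cc == c]
            for c in truth.constructs
        }
        return ds.panels, words, truth

    assert lexicons is not None
    panels: dict[str, FrequencyPanel] = {}
    for corpus in config.corpora:
        wanted: list[str] = []
        for construct in config.constructs:
            lex = lexicons[(construct, corpus)]
            wanted.extend(w for w in (e.word for e in lex.entries if e.include))
        wanted.append(config.common_word[corpus])
        if config.data_source == "viewer_json":
            payload = json.loads(
                (Path(config.panel_dir) / f"{corpus}.json").read_text(encoding="utf-8")
            )
            panel = parse_viewer_json(
                payload, config.year_start, config.year_end, language=corpus
            )
            panels[corpus] = panel.subset([w for w in wanted if w in panel.words])
        elif config.data_source == "raw_tsv":
            base = Path(config.panel_dir)
            totals = parse_totalcounts(
                (base / f"{corpus}.totalcounts.csv").read_text(encoding="utf-8")
            )
            with (base / f"{corpus}.tsv").open(encoding="utf-8") as fh:
                panels[corpus] = parse_raw_ngram(
                    fh, totals, config.year_start, config.year_end, wanted,
                    language=corpus,
                )
        else:  # cache
            panels[corpus] = fetch_panel(
                wanted, corpus, config.year_start, config.year_end,
                cache_dir=config.cache_dir, smoothing=config.smoothing,
            )
    return panels, {}, None


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full study pipeline and write all artifacts.

    Stages: load word lists (or take them from the synthetic truth), build
    panels, adjust + z-transform + aggregate into composites, pool across
    corpora, correlate (pooled and per corpus, control construct last), and
    compute per-word rolling means with trend labels.  Soft issues (dropped
    zero-variance words) accumulate in the manifest; hard errors abort with
    a stage-tagged message.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}

    def _stage(name: str):
        log.info("stage %s ...", name)
        timers[name] = time.perf_counter()

    def _done(name: str):
        log.info("stage %s done in %.2fs", name, time.perf_counter() - timers[name])

    # --- lexicons ---------------------------------------------------------
    _stage("lexicon")
    lexicons: dict[tuple[str, str], Lexicon] = {}
    if config.data_source != "synthetic":
        for construct, paths in config.constructs.items():
            for corpus in config.corpora:
                lexicons[(construct, corpus)] = load_lexicon(
                    paths[corpus], construct, corpus
                )
    _done("lexicon")

    # --- panels -----------------------------------------------------------
    _stage("panels")
    panels, synth_words, truth = build_panels(config, lexicons)
    common_words = (
        {corpus: truth.common_word for corpus in config.corpora}
        if truth is not None
        else dict(config.common_word)
    )
    _done("panels")

    # --- normalize --------------------------------------------------------
    _stage("normalize")
    per_language: dict[str, list[CompositeSeries]] = {}
    dropped: list[dict] = []
    construct_names = (
        list(truth.constructs) if truth is not None else list(config.constructs)
    )
    word_map: dict[tuple[str, str], list[str]] = {}
    for corpus in config.corpora:
        adjusted = common_word_adjust(panels[corpus], common_words[corpus])
        comps: list[CompositeSeries] = []
        for construct in construct_names:
            if truth is not None:
                words = synth_words[construct]
            else:
                lex = lexicons[(construct, corpus)]
                words = [e.word for e in lex.entries if e.include]
            word_map[(construct, corpus)] = words
            comp = composite(
                adjusted,
                words,
                construct=construct,
                aggregation=config.aggregation,
                zero_variance_policy=config.zero_variance_policy,
            )
            if comp.dropped_words:
                dropped.append(
                    {
                        "construct": construct,
                        "language": corpus,
                        "words": list(comp.dropped_words),
                    }
                )
            comps.append(comp)
        per_language[corpus] = comps
    pooled = [
        pool_languages([per_language[c][i] for c in config.corpora])
        for i in range(len(construct_names))
    ]
    _done("normalize")

    # --- trend statistics -------------------------------------------------
    _stage("trend")
    control = config.control_construct if config.control_construct in construct_names else None
    matrices: dict[str, CorrelationMatrix] = {
        "pooled": correlation_matrix(pooled, control_construct=control)
    }
    for corpus in config.corpora:
        matrices[corpus] = correlation_matrix(
            per_language[corpus], control_construct=control
        )
    rolling_rows = []
    for corpus in config.corpora:
        panel = panels[corpus]
        for construct in construct_names:
            for word in word_map[(construct, corpus)]:
                roll = rolling_mean(
                    panel.series(word),
                    window=config.rolling_window,
                    word=word,
                    language=corpus,
                    construct=construct,
                )
                label = trend_label(roll)
                for y, v in zip(roll.years, roll.values):
                    rolling_rows.append(
                        {
                            "language": corpus,
                            "construct": construct,
                            "word": word,
                            "window": config.rolling_window,
                            "year": int(y),
                            "rolling_mean": float(v),
                            "trend": label,
                        }
                    )
    _done("trend")

    # --- artifacts --------------------------------------------------------
    _stage("write")
    paths: dict[str, str] = {}

    panels_frame = pd.concat(
        [panels[c].to_long() for c in config.corpora], ignore_index=True
    )
    paths["panels"] = str(out / "panels.csv")
    panels_frame.to_csv(paths["panels"], index=False, lineterminator="\n")

    comp_rows = []
    for comp in [c for comps in per_language.values() for c in comps] + pooled:
        for y, v in zip(comp.years, comp.values):
            comp_rows.append(
                {
                    "construct": comp.construct,
                    "language": comp.language,
                    "year": int(y),
                    "value": float(v),
                    "n_words": comp.n_words,
                    "n_languages": comp.n_languages,
                }
            )
    paths["composites"] = str(out / "composites.csv")
    pd.DataFrame(comp_rows).to_csv(paths["composites"], index=False, lineterminator="\n")

    corr_frame = pd.concat(
        [matrices["pooled"].to_frame()]
        + [matrices[c].to_frame() for c in config.corpora],
        ignore_index=True,
    )
    paths["correlations"] = str(out / "correlations.csv")
    corr_frame.to_csv(paths["correlations"], index=False, lineterminator="\n")

    paths["rolling"] = str(out / "rolling.csv")
    pd.DataFrame(rolling_rows).to_csv(paths["rolling"], index=False, lineterminator="\n")

    if truth is not None:
        paths["truth"] = str(out / "truth.json")
        truth.to_json(paths["truth"])

    manifest = {
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            config.to_canonical_json().encode()
        ).hexdigest(),
        "seed": config.seed,
        "ngramtrends_version": __version__,
        "dropped_words": dropped,
        "artifacts": sorted(paths),
    }
    paths["manifest"] = str(out / "manifest.json")
    Path(paths["manifest"]).write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    _done("write")

    return RunReport(paths=paths, manifest=manifest, composites=pooled, matrices=matrices)
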