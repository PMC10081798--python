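"""Frequency panels and their Google Ngram ingestion paths.

A :class:`FrequencyPanel` holds per-word yearly *relative* frequencies for
one corpus, stored in percent of the corpus's total tokens for that year
(a word making up 1% of all tokens in 1990 stores ``1.0`` at 1990).  Panels
can be assembled from three sources:

* Ngram Viewer JSON exports (``parse_viewer_json``) — the Viewer reports
  fractions, which are converted to percent on ingestion;
* raw published ngram files plus their totalcounts sidecar
  (``parse_raw_ngram``) — frequency = 100 x match_count / total_tokens;
* a cache-first online fetcher (``fetch_panel``).

Missing (word, year) cells are filled with 0.0 — a word absent from every
book scanned in a year genuinely has zero relative frequency — and marked
unobserved so the analysis can report coverage.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyPanel",
    "TotalCounts",
    "PanelError",
    "parse_viewer_json",
    "parse_totalcounts",
    "parse_raw_ngram",
    "fetch_panel",
    "read_panel_csv",
]

log = logging.getLogger(__name__)


class PanelError(ValueError):
    """Malformed or internally inconsistent frequency-panel content."""


@dataclass
class FrequencyPanel:
    """Per-word yearly relative frequencies (percent) for one corpus.

    ``data`` is a DataFrame indexed by a contiguous ascending run of years
    with one column per word; ``observed`` (same shape, boolean) marks cells
    backed by source records rather than zero-filled.
    """

    language: str
    data: pd.DataFrame
    observed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            return
        years = np.asarray(idx, dtype=int)
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise PanelError(f"{self.language}: year index not contiguous ascending")
        if self.data.isna().any().any():
            raise PanelError(f"{self.language}: NaN frequencies")
        if (self.data.to_numpy() < 0).any():
            raise PanelError(f"{self.language}: negative frequencies")
        self.data.index = pd.Index(years, name="year")
        if self.observed is not None and self.observed.shape != self.data.shape:
            raise PanelError(f"{self.language}: observed mask shape mismatch")

    @property
    def words(self) -> list[str]:
        return list(self.data.columns)

    @property
    def year_start(self) -> int:
        return int(self.data.index[0])

    @property
    def year_end(self) -> int:
        return int(self.data.index[-1])

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def series(self, word: str) -> pd.Series:
        if word not in self.data.columns:
            raise KeyError(f"{word!r} not in panel for {self.language}")
        return self.data[word]

    def subset(self, words: Sequence[str]) -> "FrequencyPanel":
        missing = [w for w in words if w not in self.data.columns]
        if missing:
            raise PanelError(f"{self.language}: words absent from panel: {missing}")
        obs = self.observed[list(words)] if self.observed is not None else None
        return FrequencyPanel(self.language, self.data[list(words)].copy(), obs)

    def to_long(self) -> pd.DataFrame:
        """Long format: language, word, year, frequency_percent, observed_flag."""
        obs = (
            self.observed
            if self.observed is not None
            else pd.DataFrame(True, index=self.data.index, columns=self.data.columns)
        )
        rows = self.data.stack().rename("frequency_percent").reset_index()
        rows.columns = ["year", "word", "frequency_percent"]
        rows["observed_flag"] = obs.stack().reset_index(drop=True)
        rows.insert(0, "language", self.language)
        return rows[["language", "word", "year", "frequency_percent", "observed_flag"]]

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "FrequencyPanel":
        languages = frame["language"].unique()
        if len(languages) != 1:
            raise PanelError(f"expected one language, got {list(languages)}")
        data = frame.pivot(index="year", columns="word", values="frequency_percent")
        data = data.sort_index()
        data.columns.name = None
        obs = None
        if "observed_flag" in frame.columns:
            obs = frame.pivot(index="year", columns="word", values="observed_flag")
            obs = obs.sort_index().astype(bool)
            obs.columns.name = None
        if data.isna().any().any():
            data = data.fillna(0.0)
        return cls(str(languages[0]), data.astype(float), obs)


def read_panel_csv(path: str | Path) -> FrequencyPanel:
    return FrequencyPanel.from_long(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Viewer JSON

def parse_viewer_json(
    payload, year_start: int, year_end: int, language: str = "unknown"
) -> FrequencyPanel:
    """Parse an Ngram Viewer response (list of ``{ngram, timeseries}``).

    Viewer time series are fractions of the corpus; they are converted to
    percent here.  ``_INF`` parent entries and ``(All)`` aggregates keep
    their verbatim ngram labels, so they never collide with plain forms.
    """
    if isinstance(payload, str):
        payload = json.loads(payload)
    n_years = year_end - year_start + 1
    if n_years <= 0:
        raise PanelError(f"empty year range {year_start}..{year_end}")
    years = np.arange(year_start, year_end + 1)
    columns: dict[str, np.ndarray] = {}
    for entry in payload:
        name = entry["ngram"]
        ts = np.asarray(entry["timeseries"], dtype=float)
        if ts.shape != (n_years,):
            raise PanelError(
                f"{name!r}: timeseries length {ts.size} != year span {n_years}"
            )
        if (ts < 0).any():
            raise PanelError(f"{name!r}: negative frequency value")
        columns[name] = ts * 100.0  # fraction -> percent
    if not columns:
        log.warning("empty Viewer payload for %s (%d-%d)", language, year_start, year_end)
    data = pd.DataFrame(columns, index=pd.Index(years, name="year"))
    return FrequencyPanel(language=language, data=data)


# ---------------------------------------------------------------------------
# Raw ngram files + totalcounts

@dataclass(frozen=True)
class TotalCounts:
    """Per-year corpus totals (the relative-frequency denominator)."""

    match_counts: Mapping[int, int]
    page_counts: Mapping[int, int] = field(default_factory=dict)
    volume_counts: Mapping[int, int] = field(default_factory=dict)

    def total(self, year: int) -> int:
        try:
            t = self.match_counts[year]
        except KeyError:
            raise PanelError(f"no total token count for year {year}") from None
        if t <= 0:
            raise PanelError(f"non-positive total token count for year {year}")
        return t


def parse_totalcounts(text: str) -> TotalCounts:
    """Parse a totalcounts CSV: ``year,match_count,page_count,volume_count``."""
    match, pages, vols = {}, {}, {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip().rstrip(",")
        if not line or line.startswith("#") or line.startswith("year"):
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise PanelError(f"totalcounts line {lineno}: expected 4 fields")
        try:
            year, mc, pc, vc = (int(p) for p in parts)
        except ValueError:
            raise PanelError(f"totalcounts line {lineno}: non-integer field") from None
        match[year], pages[year], vols[year] = mc, pc, vc
    return TotalCounts(match, pages, vols)


def parse_raw_ngram(
    lines: Iterable[str],
    totals: TotalCounts,
    year_start: int,
    year_end: int,
    words: Sequence[str],
    language: str = "unknown",
) -> FrequencyPanel:
    """Build a panel from raw ngram records (``ngram\\tyear\\tmatch\\tvolumes``).

    frequency(word, year) = 100 x match_count(word, year) / total_tokens(year).
    Years without records become 0.0 and are marked unobserved; only the
    requested ``words`` are retained.
    """
    years = np.arange(year_start, year_end + 1)
    denominators = np.array([totals.total(int(y)) for y in years], dtype=float)
    wanted = {w: i for i, w in enumerate(words)}
    counts = np.zeros((len(years), len(words)), dtype=float)
    seen = np.zeros_like(counts, dtype=bool)
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise PanelError(f"raw ngram line {lineno}: expected 4 tab-separated fields")
        ngram, y_s, mc_s, _vc_s = parts
        if ngram not in wanted:
            continue
        try:
            year, mc = int(y_s), int(mc_s)
            int(_vc_s)
        except ValueError:
            raise PanelError(f"raw ngram line {lineno}: non-integer count") from None
        if mc < 0:
            raise PanelError(f"raw ngram line {lineno}: negative match_count")
        if year_start <= year <= year_end:
            i, j = year - year_start, wanted[ngram]
            counts[i, j] += mc
            seen[i, j] = True
    unseen = [w for w, j in wanted.items() if not seen[:, j].any()]
    if unseen:
        log.warning("%s: no records in %d-%d for %s (zero-filled)",
                    language, year_start, year_end, unseen)
    data = pd.DataFrame(
        100.0 * counts / denominators[:, None],
        index=pd.Index(years, name="year"),
        columns=list(words),
    )
    obs = pd.DataFrame(seen, index=data.index, columns=data.columns)
    return FrequencyPanel(language=language, data=data, observed=obs)


# ---------------------------------------------------------------------------
# Cache-first fetcher

VIEWER_URL = "https://books.google.com/ngrams/json"


def _default_fetcher(url: str, retries: int = 3, backoff: float = 2.0) -> str:
    last: Exception | None = None
    for attempt in range(retries):
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                return resp.read().decode("utf-8")
        except Exception as exc:  # noqa: BLE001 - network errors vary widely
            last = exc
            time.sleep(backoff * (2**attempt))
    raise PanelError(f"fetch failed after {retries} attempts: {url}: {last}")


def _cache_key(word: str, corpus: str, year_start: int, year_end: int, smoothing: int) -> str:
    safe = urllib.parse.quote(word, safe="")
    return f"{corpus}__{year_start}-{year_end}__s{smoothing}__{safe}.json"


def fetch_panel(
    words: Sequence[str],
    corpus: str,
    year_start: int,
    year_end: int,
    cache_dir: str | Path,
    smoothing: int = 0,
    fetcher: Callable[[str], str] | None = None,
) -> FrequencyPanel:
    """Assemble a panel from cache-first Viewer queries.

    Every response is persisted verbatim to ``cache_dir`` before parsing, so
    a complete cache makes the call a pure function of its arguments and no
    network is touched.  Smoothing defaults to 0 (raw yearly values) since
    smoothing would leak autocorrelation into downstream correlations.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    payloads: list[dict] = []
    missing: list[str] = []
    for word in words:
        path = cache / _cache_key(word, corpus, year_start, year_end, smoothing)
        if not path.exists():
            if fetcher is None:
                fetcher = _default_fetcher
            query = urllib.parse.urlencode(
                {
                    "content": word,
                    "year_start": year_start,
                    "year_end": year_end,
                    "corpus": corpus,
                    "smoothing": smoothing,
                }
            )
            try:
                text = fetcher(f"{VIEWER_URL}?{query}")
            except Exception as exc:  # noqa: BLE001
                log.error("fetch failed for %r: %s", word, exc)
                missing.append(word)
                continue
            path.write_text(text, encoding="utf-8")
        entries = json.loads(path.read_text(encoding="utf-8"))
        if not entries:
            # Viewer returns [] for words absent from the corpus
            payloads.append({"ngram": word,
                             "timeseries": [0.0] * (year_end - year_start + 1)})
        else:
            payloads.extend(entries)
    if missing:
        raise PanelError(f"could not fetch (no cache, network failed): {missing}")
    return parse_viewer_json(payloads, year_start, year_end, language=corpus)
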