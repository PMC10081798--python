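# ngramtrends

Lexicon-based construct indices and trend correlations from Google Books
Ngram frequency panels.

Culturomics studies track societal attention to a psychological construct —
anxiety, depression, digitalization — by following the yearly relative
frequency of a curated word list through a digitized-book corpus.
`ngramtrends` implements that pipeline end to end for researchers who want
it reproducible and testable rather than spreadsheet-bound:

* **Word lists as data.** Each construct × language list is an editable TSV
  carrying the human curation outcomes (include flags, exclusion reasons
  such as `double_meaning` or `broader_semantic`), plus optional inflection
  sets for a dominance consistency check via the Ngram Viewer's `_INF` tag.
* **Panels from three sources.** Ngram Viewer JSON exports, raw published
  ngram files + totalcounts sidecars, or a cache-first online fetcher.
  Frequencies are stored in percent of the corpus's yearly tokens.
* **Normalization.** For each word $w$ in year $t$,

  $$a_w(t) = \frac{f_w(t)}{f_{\mathrm{common}}(t)}, \qquad
    z_w(t) = \frac{a_w(t) - \bar a_w}{s_{a_w}}, \qquad
    C(t) = \frac{1}{|W|} \sum_{w \in W} z_w(t),$$

  i.e. divide by the corpus's most frequent noun in the same year (so
  year-wise changes in corpus size — the "influx of data" — cancel exactly),
  z-transform each word over the year range (sample sd), and average over
  the list. Cross-language indices average the per-language composites.
* **Trend statistics.** Pearson $r$ between composites and calendar years
  and between composites, with two-sided p from
  $t = r\sqrt{(n-2)/(1-r^2)}$, significance stars (\* p<.05, \*\* p<.01,
  \*\*\* p<.001), Holm-adjusted p alongside, and a control construct
  (religion) ordered last in the matrix; per-word five-year rolling means as
  a non-stationarity diagnostic.
* **A seeded synthetic generator.** Log-normal word panels with per-construct
  trend slopes, a shared latent path, iid noise, and year-wise corpus
  inflation — every downstream stage is testable offline against known
  ground truth.

## Worked example

Run the full pipeline on the synthetic source (six corpora, 1970–2019,
four constructs with the default study design):

```bash
ngramtrends all --seed 42 --out results/demo
```

prints the pooled correlation matrix:

```
                          1         2         3         4
1 anxiety
2 depression       +1.00***
3 digitalization   +1.00***  +1.00***
4 Years            +0.66***  +0.66***  +0.69***
5 religion         +0.08     +0.08     +0.09     +0.18
Note. * p < .05; ** p < .01; *** p < .001.
```

Anxiety, depression and digitalization words share a latent path and a
positive log-scale trend in the generator's default design, so their
composites correlate near-perfectly with each other and strongly with
calendar years; the religion control loads on nothing and stays
non-significant. The run directory contains `panels.csv` (long-format
frequencies), `composites.csv` (per-language and pooled indices, e.g.
`anxiety,de-2019,1970,-0.688,13,1`), `correlations.csv` (r, p, n, stars,
Holm p per pair and language), `rolling.csv` (five-year rolling means with
increase/decrease/flat labels), `truth.json` (generator ground truth) and
`manifest.json` (config hash + seed: reruns are byte-identical).

The same analysis runs on real exports by setting `data_source:
viewer_json` (or `raw_tsv` / `cache`) in the YAML config; see
`src/ngramtrends/data/example_config.yaml` and the example word lists next
to it.

## Library use

```python
from ngramtrends import (SyntheticTruth, generate_panel, common_word_adjust,
                         composite, pool_languages, correlation_matrix)

ds = generate_panel(SyntheticTruth(seed=1))
adjusted = common_word_adjust(ds.panels["en-GB-2019"], ds.truth.common_word)
anx = composite(adjusted, [w for w, c in ds.word_constructs.items() if c == "anxiety"],
                construct="anxiety")
```

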