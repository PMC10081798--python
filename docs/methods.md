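# Methods

## The measurement model

The package operationalizes "societal attention to construct X" as a
composite of word frequencies in a books corpus. The raw datum is a word's
yearly *relative* frequency — its match count divided by the corpus's total
token count that year — stored in percent throughout, so numbers remain
directly comparable to how such analyses are usually reported. Only 1-grams
are analyzed: multi-word phrases are too infrequent in books corpora for
stable yearly series.

Three normalization steps turn a panel of word series into a construct
index, in this order:

1. **Most-common-word adjustment.** Every word's series is divided,
   year by year, by the series of the corpus's most frequent noun
   ("time" for British English, "Zeit" for German, ...). Relative
   frequencies already remove corpus growth in the denominator, but the
   *composition* of a growing corpus also shifts (more technical text, OCR
   changes, scanning batches). Treating such influx as a year-wise
   multiplier common to all words, the ratio to the most common word
   cancels it exactly — this is a theorem about the pipeline, verified to
   1e-9 cell-for-cell in the test suite, not an approximation.
2. **z-transformation** of each adjusted word series over the year range
   (sample standard deviation, n−1). This stops high-frequency words from
   dominating the list mean.
3. **Aggregation** over the word list, per year. The package averages;
   summing instead scales the composite by the list size, and since Pearson
   r is scale-invariant every downstream correlation is identical to below
   1e-12 (asserted in the suite). That equivalence is why "summed z-scores"
   and "list-averaged" descriptions of such composites coincide.

Adjust-then-z ordering is a design choice: it makes the influx invariance
exact. The reverse order (z first) breaks the cancellation; it is not
offered as a default, and sensitivity analyses can run the stages manually.

Cross-language pooling is the unweighted mean of per-language composites.
Weighting by corpus size would let the largest corpus dominate exactly the
construct the adjustment tries to free from corpus size.

Zero-variance words (e.g. a digitalization term before its coinage, all
zeros in early years — or in every year of a small corpus) cannot be
z-transformed. The default policy drops them per language with a logged
warning and records them in the run manifest; a `fail` policy is available
for strict runs.

## Trend statistics

Composites are correlated with calendar years (Pearson r is invariant to
the affine coding of the year index) and with each other, per language and
pooled. p-values are two-sided from the exact t transform on n−2 degrees
of freedom — the conservative default where only "p < .05/.01/.001"
thresholds are reported. Stars follow the per-cell convention of
correlation tables in this literature, i.e. without multiple-testing
correction; a Holm-adjusted p-value is written next to every cell so
readers can apply the stricter standard. The control construct (religion)
is kept in the matrix and ordered last: a word list that should not share
the hypothesized trend, guarding against pipeline artifacts that would
correlate *any* two lists.

The five-year rolling mean of each word's raw series is a qualitative
non-stationarity diagnostic. Windows are trailing (the value at year t
averages t−4..t), keeping the diagnostic causal; a centered alignment is a
flag away. The increase/decrease/flat label uses the OLS slope of the
windowed means with a threshold of 1% of the series' value range per step —
the classification is inherently qualitative, and the threshold is exposed.
Exactly constant series are flat by definition.

A deliberately uncomfortable test (`test_trending_series_inflate_significance`)
documents why the control construct matters: two constructs given equal
deterministic trends but fully independent noise are declared significantly
correlated far above the nominal 5% rate. Trend correlations on
non-stationary series over-reject; differencing or formal stationarity
tests are out of scope here, and the control-list comparison is the
pipeline's guard.

## The synthetic generator

`generate_panel` emulates multi-language ngram panels with known ground
truth. Word w of construct c in year t gets

    f(w, t) = inflation(t) · exp(α_w + slope_c · t + λ_c · L(t) + ε_{w,t})

* `α_w ~ N(log 1e-3, 0.5)`: baseline log-levels around 10⁻³ percent, the
  order of magnitude of mid-frequency content words;
* `slope_c` per year on the log scale (defaults 0.02 for anxiety and
  depression, 0.03 for digitalization, 0 for religion — rising use is
  multiplicative, matching the visual character of real ngram curves);
* `L(t)`: one latent path shared by all constructs with λ_c > 0, across
  all languages. Default is a Gaussian random walk rescaled to unit sample
  variance, giving realistic autocorrelation; an `iid` switch provides the
  clean regime for type-I-error experiments (trend correlation behaves
  very differently under the two, so both must be testable);
* `ε ~ N(0, 0.15²)` iid per word-year;
* `inflation(t) = exp(0.03 t)` by default, a ~4.5× corpus growth over 50
  years applied to every word, emulating the influx the adjustment removes;
* the designated most common word is generated at 5.0 percent — orders of
  magnitude above every list word — subject to the same inflation, and the
  generator errors out if it ever fails to dominate.

Default word counts follow the published final lists of this study design:
13 + 13 anxiety/depression words, 33 digitalization words, 19 religion
control words, over 50 years (1970–2019) and six corpora.

The most common word's own sampling noise defaults to zero
(`common_word_noise_sd = 0`): at several percent of a billion-token corpus
its relative sampling error is negligible, and a noisy denominator would
inject spurious correlation between otherwise independent constructs —
the parameter exists for sensitivity work. What the generator does *not*
emulate: OCR error, corpus composition shifts that hit words unequally
(those would not cancel), word births/deaths (beyond what zero-variance
handling covers), and cross-language lexical dependence beyond the shared
latent path. Passing tests therefore certify the pipeline's arithmetic and
statistical calibration on the stated model, not the semantic validity of
any real word list.

## Numerical and validation choices

* Pearson r is clamped to [−1, 1] against floating-point overshoot; exact
  ties in the inflection dominance check break lexicographically.
* Brute-force references (`_bruteforce.py`) — explicit-sums Pearson with a
  t-CDF p, two-pass z-score, loop rolling mean, and a direct Monte-Carlo
  simulation of the generative formula — share no code with the
  implementations they validate and back both the test suite and
  `scripts/acceptance.py`.
* Calibration experiments use one language, two constructs of 10 words,
  50 years: large enough for the asymptotics that matter, small enough
  that 10,000-replicate null simulations finish in well under a minute.
  The latent-recovery experiment sets `noise_sd = 0.5` and
  `λ = √0.1 ≈ 0.316`, putting the population composite–composite
  correlation λ²/(λ² + σ²/n_words) at ≈ 0.8 up to log-normal curvature;
  the pipeline's mean estimate over 200 replicates is compared to the
  brute-force oracle, not to the closed form.
* All simulations derive per-replicate seeds from one master seed via
  `numpy.random.SeedSequence`; identical seeds reproduce every artifact
  byte for byte (asserted end to end through the CLI).

## Limitations

Correlation between trending composites is evidence of co-movement, not
cause; the package computes the diagnostics (control construct, rolling
means, Holm column) but no detrended or differenced re-analysis. The
shipped word lists are small illustrative fixtures, not validated research
instruments. The online fetcher respects the public Viewer endpoint's
informal status: cache-first, bounded retries, and everything parseable
from offline exports without it.
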