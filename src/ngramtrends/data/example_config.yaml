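# Example run configuration: synthetic panels for the six study corpora.
# Word counts, slopes and loadings below override the generator defaults;
# remove the `synthetic` block to use them.
corpora: [en-GB-2019, de-2019, es-2019, ru-2019, fr-2019, it-2019]
year_start: 1970
year_end: 2019
data_source: synthetic
seed: 42
control_construct: religion
aggregation: mean
zero_variance_policy: drop
smoothing: 0
rolling_window: 5
out_dir: results
synthetic:
  noise_sd: 0.15
  inflation_growth: 0.03
  latent: walk
  constructs:
    anxiety: {n_words: 13, trend_slope: 0.02, latent_loading: 0.8}
    depression: {n_words: 13, trend_slope: 0.02, latent_loading: 0.8}
    digitalization: {n_words: 33, trend_slope: 0.03, latent_loading: 0.8}
    religion: {n_words: 19, trend_slope: 0.0, latent_loading: 0.0}
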