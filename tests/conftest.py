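import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ngramtrends.ngram_io import FrequencyPanel
from ngramtrends.synthetic import ConstructSpec, SyntheticTruth, generate_panel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def write_lexicon_tsv(path, rows):
    """rows: iterable of (word, include, reason[, notes[, inflections]])."""
    lines = ["word\tinclude\texclusion_reason\tnotes\tinflections"]
    for row in rows:
        row = list(row) + [""] * (5 - len(row))
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def make_panel():
    """Build a FrequencyPanel from a {word: values} mapping."""

    def _make(columns, year_start=1970, language="en-GB-2019", observed=None):
        n = len(next(iter(columns.values())))
        idx = pd.Index(np.arange(year_start, year_start + n), name="year")
        data = pd.DataFrame({w: np.asarray(v, float) for w, v in columns.items()},
                            index=idx)
        obs = None
        if observed is not None:
            obs = pd.DataFrame(observed, index=idx, columns=data.columns)
        return FrequencyPanel(language=language, data=data, observed=obs)

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """A two-construct, one-language synthetic dataset with shared latent."""
    truth = SyntheticTruth(
        seed=123,
        n_years=50,
        languages=("en-GB-2019",),
        constructs={
            "a": ConstructSpec(8, trend_slope=0.01, latent_loading=0.6),
            "b": ConstructSpec(8, trend_slope=0.0, latent_loading=0.6),
        },
        noise_sd=0.2,
    )
    return generate_panel(truth)
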