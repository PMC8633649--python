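import numpy as np
import pytest

from metapi.synthetic_data import CorpusSpec, generate_corpus


@pytest.fixture()
def rng():
    return np.random.default_rng(20210731)


@pytest.fixture(scope="session")
def default_corpus():
    """One default-spec synthetic corpus (121 reviews) with its truth table."""
    records, truth = generate_corpus(CorpusSpec(seed=42))
    return records, truth


# Table 1 per-year counts (not reported, reported) of the reference corpus;
# used as in-memory input for the continuous-covariate analyses.
YEAR_COUNTS = {
    2012: (0, 1), 2013: (2, 1), 2014: (5, 1), 2015: (6, 2), 2016: (11, 3),
    2017: (18, 4), 2018: (21, 4), 2019: (16, 5), 2020: (17, 2), 2021: (2, 0),
}


def year_observations():
    xs, ys = [], []
    for year, (n_not, n_rep) in YEAR_COUNTS.items():
        xs += [year] * (n_not + n_rep)
        ys += [False] * n_not + [True] * n_rep
    return xs, ys
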