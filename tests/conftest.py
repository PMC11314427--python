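import numpy as np
import pandas as pd
import pytest

from nichecol.data import validate_bundle


def make_bundle(counts: dict, days=None, phyla=None, env=None):
    """Build a validated bundle from a {taxon: [counts...]} dict."""
    cdf = pd.DataFrame(counts).T
    cdf.index.name = "taxon"
    r = cdf.shape[1]
    cdf.columns = [f"s{j+1:02d}" for j in range(r)]
    if days is None:
        days = [3] * r
    meta = pd.DataFrame(
        {"sample": cdf.columns, "day": days, "replicate": list(range(1, r + 1))}
    ).set_index("sample")
    taxa = pd.Series(phyla, name="phylum") if phyla else None
    edf = None
    if env is not None:
        edf = pd.DataFrame(env, index=cdf.columns)
    return validate_bundle(cdf, meta, taxa, edf)


@pytest.fixture
def small_bundle():
    return make_bundle(
        {"spA": [2, 2, 0, 0], "spB": [1, 2, 3, 4], "spC": [4, 0, 0, 0]},
        days=[3, 3, 6, 6],
        phyla={"spA": "Heterokontophyta", "spB": "Chlorophyta", "spC": "Heterokontophyta"},
    )


@pytest.fixture(scope="session")
def random_count_matrices():
    """30 random 8-species x 6-sample non-negative integer matrices with no
    empty species row and no empty sample column."""
    rng = np.random.default_rng(2024)
    mats = []
    while len(mats) < 30:
        m = rng.integers(0, 12, size=(8, 6))
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all():
            mats.append(m)
    return mats


def to_counts_df(mat):
    return pd.DataFrame(
        mat,
        index=[f"sp{i+1}" for i in range(mat.shape[0])],
        columns=[f"s{j+1}" for j in range(mat.shape[1])],
    )
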