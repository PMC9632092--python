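import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def bimodal_sample(rng):
    """Well-separated two-mode sample (means 3 and 8)."""
    return np.concatenate(
        [rng.normal(3.0, 0.7, 120), rng.normal(8.0, 0.9, 120)]
    )


@pytest.fixture
def tailed_sample(rng):
    """N(5,0.8) bulk of 85 points plus 15 uniform high-tail points."""
    return np.concatenate([rng.normal(5.0, 0.8, 85), rng.uniform(8, 12, 15)])


@pytest.fixture
def three_gene_matrix():
    """samples x genes frame with planted unimodal / bimodal / tailed genes."""
    rng = np.random.default_rng(1)
    n = 120
    uni = rng.normal(7.0, 0.8, n)
    bim = np.concatenate([rng.normal(4.0, 0.6, n // 2),
                          rng.normal(9.0, 0.7, n - n // 2)])
    rng.shuffle(bim)
    tail = np.concatenate([rng.normal(6.0, 0.8, n - 18),
                           rng.uniform(8.0, 12.0, 18)])
    rng.shuffle(tail)
    return pd.DataFrame(
        {"GENE_UNI": uni, "GENE_BIM": bim, "GENE_TAIL": tail},
        index=[f"s{i}" for i in range(n)],
    )
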