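import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_locus_candidates():
    """Two loci with a clear top gene each."""
    return pd.DataFrame(
        {
            "gene_id": ["A", "B", "C", "D"],
            "locus_id": ["L1", "L1", "L2", "L2"],
            "posterior": [0.9, 0.2, 0.7, 0.1],
        }
    )
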