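import numpy as np
import pandas as pd
import pytest

import clonesense as cs


@pytest.fixture
def confetti():
    """Four-color Confetti-like scheme with unequal frequencies."""
    return cs.ColorScheme(("CFP", "RFP", "YFP", "GFP"), (0.3, 0.3, 0.3, 0.1))


@pytest.fixture
def small_table():
    """Three clusters, two samples, 2D."""
    df = pd.DataFrame({
        "sample_id": ["A", "A", "B"],
        "cluster_id": ["c1", "c2", "c3"],
        "color": ["RFP", "YFP", "RFP"],
        "x": [0.0, 1.0, 5.0],
        "y": [0.0, 0.5, 5.0],
        "size": [3, 2, 7],
    })
    return cs.ClusterTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
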