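import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def orthogonal_templates(rng):
    """Two orthonormal, average-referenced 64-channel topographies."""
    t1 = rng.normal(size=64)
    t1 -= t1.mean()
    t1 /= np.linalg.norm(t1)
    t2 = rng.normal(size=64)
    t2 -= t2.mean()
    t2 -= (t2 @ t1) * t1
    t2 /= np.linalg.norm(t2)
    return t1, t2


@pytest.fixture
def toy_cell_table():
    """Small long-format 2x2 within table with a known interaction."""
    import pandas as pd

    rows = []
    cells = {
        ("pre", "go"): [60, 55, 70, 65],
        ("pre", "nogo"): [62, 54, 71, 66],
        ("post", "go"): [58, 52, 67, 64],
        ("post", "nogo"): [50, 45, 60, 55],
    }
    for (sess, cat), vals in cells.items():
        for s, v in enumerate(vals):
            rows.append((s, sess, cat, float(v)))
    return pd.DataFrame(rows, columns=["subject", "session", "category", "value"])
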