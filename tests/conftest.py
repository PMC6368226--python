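import numpy as np
import pandas as pd
import pytest

from emtsig.expression import ExpressionMatrix
from emtsig.signature import Signature
from emtsig.simulate import SimulationConfig


@pytest.fixture
def tiny_matrix():
    """3 probesets × 4 samples with distinct values."""
    vals = pd.DataFrame(
        [[5.0, 5.2, 6.1, 6.3],
         [7.0, 7.1, 6.5, 6.4],
         [4.0, 4.1, 4.2, 4.3]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(vals, pd.Series(["GA", "GB", "GA"], index=vals.index))


@pytest.fixture
def small_signature():
    """20-probeset signature with alternating directions."""
    entries = pd.DataFrame({
        "probeset_id": [f"SP{i:02d}" for i in range(20)],
        "gene_symbol": [f"GENE{i:02d}" for i in range(20)],
        "direction": [1 if i % 2 == 0 else -1 for i in range(20)],
        "provenance": "algorithmic",
    })
    return Signature(entries, name="test-sig")


@pytest.fixture
def fast_sim():
    """Default study design with fewer null probesets, for quick unit tests."""
    cfg = SimulationConfig()
    cfg.probesets.n_null = 100
    cfg.cohort.n_null_probesets = 30
    cfg.colon.n_null_probesets = 30
    return cfg


def make_cellline_ratio_frame(rng, n_probesets=50):
    """Plain random log-ratio matrix for invariance checks."""
    vals = pd.DataFrame(
        rng.normal(0, 1, (n_probesets, 24)),
        index=[f"R{i:03d}" for i in range(n_probesets)],
        columns=[f"C{i:02d}" for i in range(24)],
    )
    return ExpressionMatrix(vals)
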