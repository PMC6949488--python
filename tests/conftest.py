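import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tmesig.signatures import AXES, DEFAULT_PANEL

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def panel_matrix(rng):
    """Random log2 matrix containing every prototype gene plus extras."""
    genes = [g for axis in AXES for g in DEFAULT_PANEL.genes(axis)]
    genes += [f"EXTRA{i:02d}" for i in range(10)]
    samples = [f"S{i:02d}" for i in range(12)]
    values = rng.normal(8.0, 2.0, (len(genes), len(samples)))
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def score_frame(rng):
    """Independent random scores for 40 samples."""
    samples = [f"S{i:02d}" for i in range(40)]
    return pd.DataFrame(
        rng.normal(size=(40, 3)),
        index=samples,
        columns=["neutrophil", "tcell", "tgfb"],
    )
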