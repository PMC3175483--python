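import numpy as np
import pytest

from immunosig.arraydata import IntensityMatrix, median_normalize_log10
from immunosig.synthesize import generate, small_config


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_matrix():
    """2 samples x 3 peptides with values 1..6."""
    return IntensityMatrix(
        values=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        sample_ids=["s1", "s2"],
        group_labels=["a", "b"],
        peptide_ids=["p1", "p2", "p3"],
    )


@pytest.fixture(scope="session")
def planted_experiment():
    """One-factor two-group synthetic experiment with a strong shift."""
    cfg = small_config(seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def planted_normalized(planted_experiment):
    x, _ = planted_experiment
    return median_normalize_log10(x)
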