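import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from keydriver.io import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(values: np.ndarray, n1: int, n2: int,
                genes=None) -> ExpressionMatrix:
    """Wrap a (genes x samples) array as a two-group ExpressionMatrix
    with the first n1 columns 'control' and the next n2 'disease'."""
    n_genes = values.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n1)] + [f"d{i}" for i in range(n2)]
    design = {s: ("control" if s.startswith("c") else "disease")
              for s in samples}
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
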