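import numpy as np
import pandas as pd
import pytest

from stressdecomp.design import DEFAULT_DESIGN, ExpressionSet


@pytest.fixture(scope="session")
def default_design():
    return DEFAULT_DESIGN


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expression(values, design=None, stage="raw"):
    """Small ExpressionSet helper for unit tests."""
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    if design is None:
        design = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(n_samples)],
                "arm": ["control"] * n_samples,
                "dose": ["0"] * n_samples,
                "replicate": list(range(1, n_samples + 1)),
            }
        )
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionSet(genes=genes, design=design, values=values, stage=stage)


@pytest.fixture()
def small_es():
    return make_expression([[1.0, 3.0], [2.0, 4.0]])
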