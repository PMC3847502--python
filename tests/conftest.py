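import numpy as np
import pandas as pd
import pytest

from lignotx import ExpressionMatrix, SyntheticDesign


def matrix_from_dict(data: dict[str, list[float]], columns: list[tuple[str, int]]) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from gene -> sample-value lists."""
    cols = pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"])
    return ExpressionMatrix(pd.DataFrame.from_dict(data, orient="index", columns=cols))


SIX_SAMPLES = [
    ("glucose", 1), ("glucose", 2),
    ("lactose", 1), ("lactose", 2),
    ("wheat_straw", 1), ("wheat_straw", 2),
]


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return matrix_from_dict(
        {"gA": [6.0, 6.2, 6.1, 5.9, 8.0, 8.2], "gB": [5.0, 5.1, 5.2, 4.9, 5.0, 5.1]},
        SIX_SAMPLES,
    )


@pytest.fixture
def default_design() -> SyntheticDesign:
    return SyntheticDesign(n_genes=400, replicates_per_condition=3, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
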