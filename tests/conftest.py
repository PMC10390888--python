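import numpy as np
import pandas as pd
import pytest

from nehet.core import ExpressionMatrix, FeatureMatrix, SignatureTable
from nehet.score import score_matrix
from nehet.simulate import GeneratorConfig, generate_panel


@pytest.fixture
def toy_signature():
    """Antithetical 2-gene signature: any non-constant profile scores +-1."""
    return SignatureTable(["g1", "g2"], [1.0, 2.0], [2.0, 1.0], ["NE", "non-NE"])


@pytest.fixture
def small_signature():
    """6-gene signature (3 NE + 3 non-NE) with monotone reference vectors."""
    return SignatureTable(
        ["a", "b", "c", "d", "e", "f"],
        [5.0, 6.0, 7.0, 2.0, 1.0, 1.5],
        [1.0, 2.0, 1.5, 6.0, 7.0, 5.0],
        ["NE"] * 3 + ["non-NE"] * 3,
    )


@pytest.fixture(scope="session")
def panels():
    """Default synthetic panel set at a fixed seed, shared across tests."""
    return generate_panel(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def bulk_scores(panels):
    return score_matrix(panels.bulk.matrix("expression"), panels.signature)


def make_matrix(arr, modality="rppa", features=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=features, columns=samples)
    if modality == "expression":
        return ExpressionMatrix(df)
    return FeatureMatrix(df, modality)
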