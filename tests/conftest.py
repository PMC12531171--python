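import numpy as np
import pytest

from glycosig.io import ExpressionMatrix, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_lognorm(rng):
    """A 30-gene x 20-observation log-scale matrix."""
    X = rng.normal(2.0, 1.0, size=(30, 20))
    return ExpressionMatrix(
        X,
        [f"G{i:03d}" for i in range(30)],
        [f"S{i:02d}" for i in range(20)],
        layer_tag="lognorm",
    )


@pytest.fixture
def toy_counts():
    """3 genes x 3 cells with easily hand-checked totals."""
    X = np.array(
        [
            [1.0, 0.0, 2.0],
            [1.0, 3.0, 0.0],
            [2.0, 1.0, 2.0],
        ]
    )
    return ExpressionMatrix(X, ["A", "B", "MT-CO1"], ["c1", "c2", "c3"], "counts")


@pytest.fixture
def glyc_set():
    return GeneSet("GLYC", ("G000", "G001", "G002", "G003", "G004"))
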