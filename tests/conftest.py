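import numpy as np
import pandas as pd
import pytest

from autonomy.io import ExpressionMatrix, GeneSignature


@pytest.fixture
def tiny_matrix():
    """4 genes x 4 samples with a clean step structure in g1/g2."""
    values = pd.DataFrame(
        [[1.0, 1.0, 5.0, 5.0],
         [5.0, 5.0, 1.0, 1.0],
         [2.0, 2.0, 2.0, 2.0],
         [1.0, 2.0, 3.0, 4.0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4"])
    annotations = pd.DataFrame({"group": ["A", "A", "B", "B"]},
                               index=values.columns)
    return ExpressionMatrix(values=values, annotations=annotations)


@pytest.fixture
def two_gene_signature():
    return GeneSignature(name="toy", entries=[("g1", 1), ("g2", -1)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
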