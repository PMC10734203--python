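import numpy as np
import pytest

from engep.data_model import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, cell_prefix="c", gene_prefix="g", normalized=False):
    values = np.asarray(values, dtype=float)
    cells = [f"{cell_prefix}{i}" for i in range(values.shape[0])]
    genes = [f"{gene_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, np.array(cells, dtype=object),
                            np.array(genes, dtype=object),
                            normalized=normalized)


@pytest.fixture
def small_counts():
    return make_matrix([[10, 0, 5], [1, 2, 3], [4, 4, 4]])
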