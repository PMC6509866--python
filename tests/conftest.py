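import numpy as np
import pytest

from grangersift import ExpressionMatrix, SampleLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """2 genes x 3 samples with values 1..6 row-major."""
    return ExpressionMatrix(
        gene_ids=("EGFR", "TOP2A"),
        sample_ids=("s1", "s2", "s3"),
        values=np.arange(1.0, 7.0).reshape(2, 3),
    )


@pytest.fixture
def two_class_matrix(rng):
    """30 genes x 40 samples, gene g000 separable by a large tumor shift."""
    genes = tuple(f"g{i:03d}" for i in range(30))
    samples = tuple(f"t{i}" for i in range(20)) + tuple(f"n{i}" for i in range(20))
    vals = rng.standard_normal((30, 40))
    vals[0, :20] += 10.0
    matrix = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=vals)
    labels = SampleLabels(sample_ids=samples, y=np.r_[np.ones(20, int), np.zeros(20, int)])
    return matrix, labels
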