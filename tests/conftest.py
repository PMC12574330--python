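import numpy as np
import pytest
import scipy.sparse as sp

from patchvar import ExpressionMatrix, SpotCoordinates


@pytest.fixture
def toy_line():
    """Three collinear spots one unit apart with a single feature (1, 3, 2).

    With radii 1.5 / 2.5 (no density rescaling) the patches are {2}, {1,3},
    {2}, the small/big local-mean variances are 0.75 / 0.25 on the raw scale,
    and the variance ratio is exactly 1/3.
    """
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    X = ExpressionMatrix(
        sp.csr_matrix(np.array([[1.0, 3.0, 2.0]])), ["g1"], ["s1", "s2", "s3"]
    )
    return X, coords


def random_instance(seed, n=40, m=120, d=2, sparsity=0.5):
    """Random sparse expression + uniform coordinates for oracle checks."""
    rng = np.random.default_rng(seed)
    dense = rng.poisson(3.0, size=(n, m)).astype(float)
    dense[rng.random((n, m)) > sparsity] = 0.0
    # ensure no all-zero feature so ratios are defined for every row
    zero_rows = np.flatnonzero(dense.sum(axis=1) == 0)
    for j in zero_rows:
        dense[j, rng.integers(m)] = 1.0 + rng.integers(5)
    coords = rng.uniform(0, 10 * d, size=(m, d))
    X = ExpressionMatrix(
        sp.csr_matrix(dense),
        [f"g{i}" for i in range(n)],
        [f"s{i}" for i in range(m)],
    )
    return X, SpotCoordinates(coords), dense


@pytest.fixture
def small_random_instance():
    return random_instance(seed=7)
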