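import numpy as np
import pytest

from geostatmap.core_grid import GridSpec, ObservationTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_grid():
    return GridSpec(0.0, 0.0, 1.0, 120, 120)


def random_observations(rng, n=40, p=1, extent=(0, 0, 60, 60)):
    x0, y0, x1, y1 = extent
    locs = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    vals = rng.integers(0, 2, (n, p)).astype(float)
    names = ["z"] if p == 1 else [f"z{i+1}" for i in range(p)]
    return ObservationTable(locs, vals, names)


def brute_force_ols(X, Y):
    """Independent per-cell textbook OLS: loop over cells with lstsq.

    Y is (N, M); returns beta (Q, M), sigma2 (M,), residuals (N, M).
    """
    n, m = Y.shape
    q = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    nu = n - rank
    beta = np.empty((q, m))
    sigma2 = np.empty(m)
    resid = np.empty((n, m))
    for j in range(m):
        b, *_ = np.linalg.lstsq(X, Y[:, j], rcond=None)
        r = Y[:, j] - X @ b
        beta[:, j] = b
        sigma2[j] = (r @ r) / nu
        resid[:, j] = r
    return beta, sigma2, resid, nu
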