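"""Mass-univariate general linear modelling.

The same multiple-regression model is fitted independently at every grid
cell: the design matrix X (N observations x Q regressors, built from the
observation covariates) is shared across cells, while the dependent
variable at each cell is the vector of N rasterized Gaussian responses.
Contrast t-maps are computed from the per-cell coefficients and the shared
(X'X)^- matrix.  Because t statistics are normalized effect sizes, they are
invariant to any global rescaling of the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_grid import GridSpec, ObservationTable, ResponseStack

__all__ = [
    "DesignSpec",
    "DesignMatrix",
    "MassUnivariateFit",
    "one_hot_conditions",
    "condition_order",
    "build_design",
    "fit_mass_univariate",
    "contrast_t_map",
    "condition_contrast",
]


def condition_order(p: int) -> list[tuple[int, ...]]:
    """Ordering of the 2^P spatial conditions.

    The first variable varies fastest: for P=2 the order is
    (0,0), (1,0), (0,1), (1,1).
    """
    if p < 1:
        raise ValueError("need at least one variable")
    return [tuple((i >> j) & 1 for j in range(p)) for i in range(2**p)]


def _condition_name(bits: tuple[int, ...]) -> str:
    return "cond_" + "".join(str(b) for b in bits)


def one_hot_conditions(obs: ObservationTable, threshold: float = 0.5) -> ObservationTable:
    """Map each record to its spatial condition and one-hot encode it.

    The spatial condition of a record is the P-tuple of indicators
    ``value > threshold`` (a value exactly equal to the threshold counts as
    0, i.e. "not exceeding").  The result has K = 2^P mutually exclusive
    binary dummy variables, exactly one of which is 1 per record.
    """
    if not np.all(np.isfinite(obs.values)):
        raise ValueError("one-hot encoding requires finite numeric variables")
    bits = (obs.values > threshold).astype(int)  # (N, P)
    order = condition_order(obs.p)
    index_of = {cond: i for i, cond in enumerate(order)}
    idx = np.array([index_of[tuple(row)] for row in bits])
    dummies = np.zeros((obs.n, len(order)))
    dummies[np.arange(obs.n), idx] = 1.0
    names = [_condition_name(c) for c in order]
    return ObservationTable(obs.locations.copy(), dummies, names)


@dataclass(frozen=True)
class DesignSpec:
    """Ordered model terms.

    Each term is a variable name, ``"intercept"``, or an interaction such
    as ``"z1*z2"`` (the element-wise product of the named variables).  When
    ``one_hot`` is set, the observation variables are first converted to
    one-hot spatial-condition dummies and the terms are the K condition
    columns (an explicit intercept is then inadmissible: the dummies already
    sum to one).
    """

    terms: tuple[str, ...]
    one_hot: bool = False
    one_hot_threshold: float = 0.5

    def __init__(self, terms: Sequence[str], one_hot: bool = False,
                 one_hot_threshold: float = 0.5):
        object.__setattr__(self, "terms", tuple(terms))
        object.__setattr__(self, "one_hot", one_hot)
        object.__setattr__(self, "one_hot_threshold", one_hot_threshold)
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in design")

    @classmethod
    def for_conditions(cls, p: int, threshold: float = 0.5) -> "DesignSpec":
        terms = [_condition_name(c) for c in condition_order(p)]
        return cls(terms, one_hot=True, one_hot_threshold=threshold)


@dataclass
class DesignMatrix:
    X: np.ndarray  # (N, Q)
    term_names: list[str]
    rank: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]


def build_design(obs: ObservationTable, spec: DesignSpec) -> DesignMatrix:
    """Assemble the design matrix in the spec's term order.

    Interaction columns are element-wise products of their factor columns;
    an ``intercept`` term is a column of ones.  The numerical rank is
    computed and a rank-deficient design triggers a warning (or an error
    when the deficiency is the structural intercept + full one-hot one).
    """
    if spec.one_hot:
        if "intercept" in spec.terms:
            raise ValueError(
                "a full one-hot condition design is rank deficient with an "
                "intercept (the dummies sum to one); drop the intercept"
            )
        obs = one_hot_conditions(obs, spec.one_hot_threshold)

    cols = {name: obs.values[:, i] for i, name in enumerate(obs.variable_names)}
    X = np.empty((obs.n, len(spec.terms)))
    for qi, term in enumerate(spec.terms):
        if term == "intercept":
            X[:, qi] = 1.0
        elif "*" in term:
            factors = [f.strip() for f in term.split("*")]
            col = np.ones(obs.n)
            for f in factors:
                if f not in cols:
                    raise KeyError(f"interaction term {term!r} references "
                                   f"unknown variable {f!r}")
                col = col * cols[f]
            X[:, qi] = col
        else:
            if term not in cols:
                raise KeyError(f"design term {term!r} not among variables "
                               f"{list(cols)}")
            X[:, qi] = cols[term]
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            "estimation proceeds via the pseudoinverse",
            stacklevel=2,
        )
    return DesignMatrix(X=X, term_names=list(spec.terms), rank=rank)


@dataclass
class MassUnivariateFit:
    """Per-cell ordinary-least-squares results on a grid.

    ``beta`` has shape (Q, n_rows, n_cols); ``sigma2`` and ``residuals``
    are the residual error-variance map and the N residual maps (``None``
    when the fit was run with ``keep_residuals=False``; smoothness can then
    be estimated directly from the responses).  Cells outside the analysis
    mask carry NaN.  ``degenerate`` flags masked cells whose responses were
    identically fitted (zero residual norm).
    """

    beta: np.ndarray
    sigma2: np.ndarray
    residuals: np.ndarray | None = field(repr=False)
    nu: int
    XtX_pinv: np.ndarray
    mask: np.ndarray
    grid: GridSpec | None = None

    @property
    def degenerate(self) -> np.ndarray:
        return self.mask & (self.sigma2 == 0)


def fit_mass_univariate(
    stack: ResponseStack | np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    grid: GridSpec | None = None,
    keep_residuals: bool = True,
) -> MassUnivariateFit:
    """Ordinary least squares at every masked cell.

    beta = (X'X)^- X' y, residuals r = y - X beta, sigma2 = r'r / nu with
    nu = N - rank(X).  The pseudoinverse is used throughout so that
    rank-deficient designs degrade gracefully.

    With ``keep_residuals=False`` the N residual maps are never
    materialized: the residual sum of squares is obtained from the
    sufficient statistics as y'y - beta'(X'y), which is algebraically
    identical for the least-squares solution.  This cuts the memory and
    time cost for large N substantially.
    """
    if isinstance(stack, ResponseStack):
        if len(stack.data) != 1:
            raise ValueError("fit one scale at a time; pass stack.at_scale(...)")
        if grid is None:
            grid = stack.grid
        Y3 = stack.data[0]
    else:
        Y3 = np.asarray(stack)
    if Y3.ndim != 3:
        raise ValueError("response must be an (N, n_rows, n_cols) array")
    n, n_rows, n_cols = Y3.shape
    X = design.X
    if X.shape[0] != n:
        raise ValueError(f"design has N={X.shape[0]} but response has N={n}")
    nu = n - design.rank
    if nu < 1:
        raise ValueError(f"no residual degrees of freedom (N={n}, rank={design.rank})")

    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    full_mask = bool(flat.all())

    dtype = Y3.dtype if Y3.dtype in (np.float32, np.float64) else np.float64
    if full_mask:
        Y = Y3.reshape(n, -1)  # view, no copy
    else:
        Y = Y3.reshape(n, -1)[:, flat]
    Y = Y.astype(dtype, copy=False)

    q = X.shape[1]
    XtX_pinv = np.linalg.pinv(X.T @ X)
    Xd = X.astype(dtype, copy=False)
    G = Xd.T @ Y  # (Q, M) sufficient statistic X'y per cell
    beta_m = XtX_pinv.astype(dtype) @ G  # = (X'X)^- X' y = pinv(X) y

    if keep_residuals:
        resid_m = Y - Xd @ beta_m
        rss = np.einsum("ij,ij->j", resid_m, resid_m, dtype=np.float64)
    else:
        resid_m = None
        s_yy = np.einsum("ij,ij->j", Y, Y, dtype=np.float64)
        rss = s_yy - np.einsum("qj,qj->j", G, beta_m, dtype=np.float64)
        np.clip(rss, 0.0, None, out=rss)
    sigma2_m = (rss / nu).astype(dtype)

    if full_mask:
        beta = beta_m
        sigma2 = sigma2_m
        residuals = resid_m
    else:
        beta = np.full((q, n_rows * n_cols), np.nan, dtype=dtype)
        beta[:, flat] = beta_m
        sigma2 = np.full(n_rows * n_cols, np.nan, dtype=dtype)
        sigma2[flat] = sigma2_m
        if keep_residuals:
            residuals = np.full((n, n_rows * n_cols), np.nan, dtype=dtype)
            residuals[:, flat] = resid_m
        else:
            residuals = None

    return MassUnivariateFit(
        beta=beta.reshape(q, n_rows, n_cols),
        sigma2=sigma2.reshape(n_rows, n_cols),
        residuals=None if residuals is None else residuals.reshape(n, n_rows, n_cols),
        nu=nu,
        XtX_pinv=XtX_pinv,
        mask=mask,
        grid=grid,
    )


def contrast_t_map(fit: MassUnivariateFit, c: Sequence[float]) -> np.ndarray:
    """t map of the contrast c'beta / sqrt(sigma2 * c'(X'X)^- c).

    Degenerate cells (zero residual variance) and cells outside the mask
    are NaN.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.beta.shape[0],):
        raise ValueError(f"contrast length {c.size} != Q={fit.beta.shape[0]}")
    var_c = float(c @ fit.XtX_pinv @ c)
    if var_c <= 0:
        raise ValueError("contrast is not estimable under this design (c'(X'X)^-c <= 0)")
    effect = np.tensordot(c, fit.beta, axes=(0, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.sigma2 * var_c)
    t[fit.degenerate] = np.nan
    return t


def condition_contrast(q: int, k: int) -> np.ndarray:
    """Contrast testing condition k against the mean of the other
    conditions: +1 on column k, -1/(Q-1) elsewhere."""
    if q < 2:
        raise ValueError("need at least two conditions")
    c = np.full(q, -1.0 / (q - 1))
    c[k] = 1.0
    return c
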