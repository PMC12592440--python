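"""Covariance-association testing via pairwise products (MANOCCA).

For standardized outcomes the covariance of a pair of taxa equals the mean
of their element-wise product across individuals, so the N per-individual
products act as individual-level observations of that covariance.  The test
chain is:

1. rank-normalize (optional, default on) and standardize the K taxa
   columns (mean 0, variance 1, divisor N);
2. form all K(K-1)/2 pairwise products ``P_ij = Y_i * Y_j``;
3. inverse-rank normal transform (Blom offsets) each product column;
4. reduce to ``p`` principal components, inverse-normal transform and scale
   the scores;
5. test ``Q ~ X + C`` with a single-predictor Wilks-lambda exact F test.

Because the optimal number of components is unknown a priori, the scan
re-tests over a grid of component counts (nested in one PCA fit) and the
Bonferroni thresholds account for the grid size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from ._wilks import WilksTest, residualize, wilks_lambda_single
from .datatables import AbundanceTable

__all__ = [
    "ProductMatrix",
    "PCProjection",
    "CovTest",
    "CovTestResult",
    "standardize_columns",
    "pairwise_products",
    "inverse_normal_transform",
    "transform_products",
    "fit_product_pca",
    "covariance_test",
    "manocca_scan",
    "multiple_testing_thresholds",
    "default_pc_cap",
]


@dataclass
class ProductMatrix:
    """N x M matrix of pairwise taxa products, M = K(K-1)/2.

    ``pair_index`` maps each column to its (i, j) taxa pair, i < j, in
    lexicographic order.  The column mean of a standardized-product column
    equals the sample correlation (divisor N) of the two taxa.
    """

    values: np.ndarray
    pair_index: list[tuple[int, int]]
    taxon_ids: list | None = None

    def __post_init__(self) -> None:
        m = self.values.shape[1]
        if m != len(self.pair_index):
            raise ValueError("pair_index length does not match column count")
        if self.pair_index != sorted(self.pair_index):
            raise ValueError("pair_index must be lexicographically increasing")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


@dataclass
class PCProjection:
    """PCA reduction of the (transformed) product matrix.

    ``loadings`` has unit-norm columns; ``train_means`` are the product-column
    centering offsets; ``train_quantile_maps`` (optional) store, per product
    column, the sorted raw products and their normal-quantile images so the
    inverse-normal step can be replayed on held-out data.
    """

    loadings: np.ndarray  # M x p
    explained_variance: np.ndarray
    p: int
    train_means: np.ndarray
    pair_index: list[tuple[int, int]]
    train_quantile_maps: list[tuple[np.ndarray, np.ndarray]] | None = None
    taxon_ids: list | None = None


@dataclass
class CovTest:
    """One covariance test at a fixed component count."""

    p_value: float
    betas: np.ndarray
    wilks: WilksTest
    n_samples: int
    n_components: int


@dataclass
class CovTestResult:
    """Full scan over a grid of component counts for one predictor."""

    predictor: str
    p_grid: list[int]
    p_values: np.ndarray
    optimal_p: int
    betas: np.ndarray  # at optimal_p
    n_samples: int
    projection: PCProjection
    tests: dict[int, CovTest] = field(default_factory=dict)

    @property
    def p_value(self) -> float:
        """P-value at the optimal component count (minimum over the grid)."""
        return float(self.p_values[self.p_grid.index(self.optimal_p)])


def standardize_columns(
    Y: np.ndarray, taxon_ids: list | None = None
) -> np.ndarray:
    """Center and scale each column to mean 0 / variance 1 (divisor N)."""
    Y = np.asarray(Y, dtype=float)
    means = Y.mean(axis=0)
    sds = Y.std(axis=0)  # population convention
    zero = np.nonzero(sds == 0)[0]
    if len(zero):
        names = [taxon_ids[i] for i in zero] if taxon_ids else list(zero)
        raise ValueError(f"zero-variance column(s): {names}")
    return (Y - means) / sds


def pairwise_products(Y_std: np.ndarray, taxon_ids: list | None = None) -> ProductMatrix:
    """All element-wise products ``P_ij = Y_i * Y_j`` for i < j.

    Expects standardized input, so each column mean is the sample correlation
    of the pair.
    """
    Y_std = np.asarray(Y_std, dtype=float)
    n, k = Y_std.shape
    if k < 2:
        raise ValueError(f"need at least 2 taxa to form products, got K={k}")
    iu, ju = np.triu_indices(k, k=1)
    values = Y_std[:, iu] * Y_std[:, ju]
    pair_index = list(zip(iu.tolist(), ju.tolist()))
    return ProductMatrix(values=values, pair_index=pair_index, taxon_ids=taxon_ids)


def inverse_normal_transform(v: np.ndarray) -> np.ndarray:
    """Blom inverse-rank normal transform with average ranks for ties.

    Maps each value to ``Phi^-1((rank - 3/8) / (n + 1/4))``.  Ties (e.g. the
    mass of zero products from sparse taxa) receive the average rank and
    hence share one output value.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.shape[0]
    if n < 3:
        raise ValueError(f"inverse-normal transform needs length >= 3, got {n}")
    if np.all(v == v[0]):
        raise ValueError("all-constant vector cannot be rank-normalized")
    ranks = stats.rankdata(v, method="average")
    return special.ndtri((ranks - 0.375) / (n + 0.25))


def transform_products(
    P: ProductMatrix, keep_quantile_maps: bool = False
) -> tuple[ProductMatrix, list[tuple[np.ndarray, np.ndarray]] | None]:
    """Inverse-normal transform every product column.

    When ``keep_quantile_maps`` is set, also return per-column (sorted raw
    value, normal quantile) tables for replaying the transform on new data.
    """
    raw = P.values
    out = np.empty_like(raw)
    maps: list[tuple[np.ndarray, np.ndarray]] | None = [] if keep_quantile_maps else None
    for j in range(raw.shape[1]):
        out[:, j] = inverse_normal_transform(raw[:, j])
        if maps is not None:
            xs, idx = np.unique(raw[:, j], return_index=True)
            maps.append((xs, out[idx, j].copy()))
    return (
        ProductMatrix(values=out, pair_index=list(P.pair_index), taxon_ids=P.taxon_ids),
        maps,
    )


def fit_product_pca(
    P: ProductMatrix,
    p: int,
    quantile_maps: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[PCProjection, np.ndarray]:
    """PCA on centered product columns; returns the projection and scores Q.

    ``P`` must already be inverse-normal transformed.  The N x p score
    matrix Q has each column inverse-normal transformed again and scaled to
    unit variance, as used by the covariance test.  Loadings keep unit
    Euclidean norm so squared loadings define contribution shares.
    """
    vals = P.values
    n, m = vals.shape
    if not 1 <= p <= min(n - 1, m):
        raise ValueError(f"p={p} out of range 1..min(N-1, M)={min(n - 1, m)}")
    means = vals.mean(axis=0)
    centered = vals - means
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    loadings = Vt[:p].T
    raw_scores = centered @ loadings
    Q = np.empty_like(raw_scores)
    for r in range(p):
        q = inverse_normal_transform(raw_scores[:, r])
        Q[:, r] = q / q.std()
    proj = PCProjection(
        loadings=loadings,
        explained_variance=(s[:p] ** 2) / n,
        p=p,
        train_means=means,
        pair_index=list(P.pair_index),
        train_quantile_maps=quantile_maps,
        taxon_ids=P.taxon_ids,
    )
    return proj, Q


def covariance_test(
    Q: np.ndarray, X: np.ndarray, C: np.ndarray | None = None
) -> CovTest:
    """Wilks-lambda test of a single scaled predictor on the score matrix.

    ``Q`` is residualized on an intercept plus scaled covariates ``C``; the
    scaled predictor is residualized the same way; the exact one-predictor
    F transform gives the p-value.  ``betas`` are the per-component
    regression coefficients of the residualized scores on the residualized
    predictor.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    n, p = Q.shape
    x = _scale_vector(np.asarray(X, dtype=float).ravel(), "predictor")
    C_s, c = _scale_covariates(C)
    if p >= n - c - 1:
        raise ValueError(f"p={p} >= N - c - 1 = {n - c - 1}: too many components")
    Q_res = residualize(Q, C_s)
    x_res = residualize(x, C_s).ravel()
    wt = wilks_lambda_single(Q_res, x_res, n_covariates=c)
    betas = Q_res.T @ x_res / float(x_res @ x_res)
    return CovTest(p_value=wt.p_value, betas=betas, wilks=wt,
                   n_samples=n, n_components=p)


def manocca_scan(
    Y: AbundanceTable | np.ndarray,
    X: np.ndarray,
    C: np.ndarray | None = None,
    p_grid: list[int] | None = None,
    predictor: str = "X",
    pc_cap: int | None = None,
    pre_int: bool = True,
) -> CovTestResult:
    """Run the full covariance-test chain over a grid of component counts.

    The PCA is fitted once at the largest requested component count; smaller
    counts reuse the leading components, so the grid is nested and cheap.
    ``optimal_p`` is the argmin of the p-value over the grid, ties broken to
    the smallest count.  Grid entries beyond what the sample size supports
    are truncated with a warning; the default cap is ``min(100, N // 10)``.

    With ``pre_int`` (the default) each taxon column is inverse-normal
    transformed before standardization, so the chain tests the covariance of
    rank-normalized abundances.  On heavy-tailed relative abundances this is
    what keeps the test independent of pure mean effects: a mean shift on
    the raw scale is nonlinear (multiplicative), and products of nonlinear
    mean responses correlate linearly with the predictor, whereas the
    rank-normalized response is linear in the shift and its product leak
    cancels by symmetry.
    """
    if isinstance(Y, AbundanceTable):
        Y.require_analysis_ready()
        taxon_ids: list | None = Y.taxon_ids
        vals = Y.values
    else:
        vals = np.asarray(Y, dtype=float)
        taxon_ids = None
    n, k = vals.shape
    x = np.asarray(X, dtype=float).ravel()
    if x.shape[0] != n:
        raise ValueError("predictor length does not match sample count")
    # drop degenerate taxa before standardization (exact-constant check:
    # the std of a constant column can be a nonzero rounding residue)
    constant = (vals == vals[0]).all(axis=0)
    if constant.any():
        dropped = (
            [taxon_ids[i] for i in np.nonzero(constant)[0]]
            if taxon_ids
            else np.nonzero(constant)[0].tolist()
        )
        warnings.warn(f"dropping zero-variance taxa: {dropped}", stacklevel=2)
        keep = ~constant
        vals = vals[:, keep]
        if taxon_ids:
            taxon_ids = [t for t, k_ in zip(taxon_ids, keep) if k_]
        k = vals.shape[1]
    m = k * (k - 1) // 2
    c = 0 if C is None or np.size(C) == 0 else np.atleast_2d(np.asarray(C).T).T.shape[1]
    cap = pc_cap if pc_cap is not None else min(100, n // 10)
    feasible = min(n - c - 2, n - 1, m, cap)
    if p_grid is None:
        p_grid = list(range(2, 101))
    grid = sorted({int(p) for p in p_grid})
    if any(p < 1 for p in grid):
        raise ValueError("component counts must be >= 1")
    if grid[-1] > feasible:
        warnings.warn(
            f"truncating component grid at {feasible} "
            f"(N={n}, M={m}, covariates={c}, cap={cap})",
            stacklevel=2,
        )
        grid = [p for p in grid if p <= feasible]
        if not grid:
            raise ValueError("no feasible component count in grid")
    p_max = grid[-1]
    if pre_int:
        vals = np.column_stack(
            [inverse_normal_transform(vals[:, j]) for j in range(k)]
        )
    Z = standardize_columns(vals, taxon_ids)
    P = pairwise_products(Z, taxon_ids)
    P_int, _ = transform_products(P)
    proj, Q = fit_product_pca(P_int, p_max)
    tests: dict[int, CovTest] = {}
    pvals = np.empty(len(grid))
    for idx, p in enumerate(grid):
        tests[p] = covariance_test(Q[:, :p], x, C)
        pvals[idx] = tests[p].p_value
    best = int(np.argmin(pvals))  # ties -> smallest p (grid is ascending)
    optimal_p = grid[best]
    return CovTestResult(
        predictor=predictor,
        p_grid=grid,
        p_values=pvals,
        optimal_p=optimal_p,
        betas=tests[optimal_p].betas,
        n_samples=n,
        projection=proj,
        tests=tests,
    )


def multiple_testing_thresholds(
    n_predictors: int, n_pc_models: int
) -> tuple[float, float]:
    """Bonferroni pair (stringent, suggestive) for a component-grid screen.

    stringent = 0.05 / (n_predictors * n_pc_models) counts every component
    model as an independent test; suggestive = 0.05 / n_predictors assumes
    the component models are strongly correlated.
    """
    if n_predictors < 1 or n_pc_models < 1:
        raise ValueError("counts must be >= 1")
    return 0.05 / (n_predictors * n_pc_models), 0.05 / n_predictors


def default_pc_cap(n_samples: int) -> int:
    """Default cap on the component grid: min(100, N // 10)."""
    return min(100, n_samples // 10)


def _scale_vector(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (v - v.mean()) / sd


def _scale_covariates(C: np.ndarray | None) -> tuple[np.ndarray | None, int]:
    if C is None or np.size(C) == 0:
        return None, 0
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    sds = C.std(axis=0)
    if (sds == 0).any():
        raise ValueError("zero-variance covariate column")
    return (C - C.mean(axis=0)) / sds, C.shape[1]
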