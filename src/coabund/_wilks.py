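"""Shared Wilks-lambda machinery for single-predictor multivariate tests.

Both the covariance-association test and the MANOVA baseline reduce to the
same question: after residualizing a multivariate response on covariates,
does a single scaled predictor explain variation in it?  For one hypothesis
degree of freedom Wilks' lambda admits an exact F transform, and the
determinant ratio collapses to ``1 - R^2`` of regressing the predictor on
the response columns (a rank-one determinant identity).  Keeping this in
one routine guarantees the two tests agree whenever their inputs do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WilksTest", "wilks_lambda_single", "residualize"]


@dataclass(frozen=True)
class WilksTest:
    """Result of a single-predictor Wilks-lambda test.

    ``df1 = p`` (response dimension) and ``df2 = N - p - c - 1`` where ``c``
    is the number of covariate columns (intercept excluded).
    """

    lambda_: float
    f_value: float
    df1: int
    df2: int
    p_value: float


def residualize(M: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of ``M`` on an intercept plus covariates ``C``."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n = M.shape[0]
    design = np.ones((n, 1))
    if C is not None and np.size(C) > 0:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        design = np.hstack([design, C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ coef


def wilks_lambda_single(
    Y_res: np.ndarray, x_res: np.ndarray, n_covariates: int = 0
) -> WilksTest:
    """Exact one-predictor Wilks-lambda test on pre-residualized inputs.

    Parameters
    ----------
    Y_res:
        N x p response matrix, already residualized on the covariates
        (including the intercept).
    x_res:
        Length-N predictor, residualized the same way.
    n_covariates:
        Number of covariate columns used in the residualization (intercept
        excluded); only enters the error degrees of freedom.
    """
    Y_res = np.asarray(Y_res, dtype=float)
    x_res = np.asarray(x_res, dtype=float).ravel()
    n, p = Y_res.shape
    if x_res.shape[0] != n:
        raise ValueError("predictor/response length mismatch")
    df2 = n - p - n_covariates - 1
    if df2 < 1:
        raise ValueError(
            f"insufficient error degrees of freedom: N={n}, p={p}, "
            f"c={n_covariates} gives df2={df2}; reduce the dimension"
        )
    sxx = float(x_res @ x_res)
    if sxx <= 0:
        raise ValueError("predictor has zero variance after residualization")
    # Lambda = det(E)/det(E+H) with rank-one H reduces to 1 - R^2(x ~ Y).
    G = Y_res.T @ Y_res
    b = Y_res.T @ x_res
    try:
        sol = np.linalg.solve(G, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular response cross-product matrix") from exc
    r2 = float(b @ sol) / sxx
    lam = float(np.clip(1.0 - r2, np.finfo(float).tiny, 1.0))
    f_value = (1.0 - lam) / lam * df2 / p
    p_value = float(stats.f.sf(f_value, p, df2))
    return WilksTest(lambda_=lam, f_value=f_value, df1=p, df2=df2,
                     p_value=max(p_value, np.finfo(float).tiny))
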