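"""Decomposition of a covariance-association signal into taxa contributions.

Every step of the test chain is linear, so the global statistic can be
re-attributed to the taxa pairs that drive it: the contribution of pair
(i, j) is ``phi(P_ij) = sum_r beta_r^2 (lambda_ij^(r))^2`` — squared PCA
loadings weighted by the squared per-component regression coefficients —
and a taxon's contribution ``psi(Y_i)`` sums phi over all pairs touching
it.  Because loading columns have unit norm, ``sum_ij phi = sum_r beta_r^2``
exactly.  The direction of effect per pair is read from the sign of the
regression of the raw (covariate-adjusted) product on the predictor, so it
is interpretable on the covariance scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._wilks import residualize
from .manocca import PCProjection, ProductMatrix, _scale_covariates, _scale_vector

__all__ = [
    "pair_contributions",
    "taxon_contributions",
    "direction_of_effect",
    "contribution_table",
    "weight_vs_univariate_correlation",
]


def pair_contributions(proj: PCProjection, betas: np.ndarray) -> np.ndarray:
    """Per-pair contribution ``phi = sum_r beta_r^2 lambda_r^2``, keyed by pair_index."""
    betas = np.asarray(betas, dtype=float).ravel()
    L = betas.shape[0]
    if L > proj.loadings.shape[1]:
        raise ValueError(
            f"{L} coefficients but only {proj.loadings.shape[1]} loading columns"
        )
    return (proj.loadings[:, :L] ** 2) @ (betas**2)


def taxon_contributions(
    pair_phi: np.ndarray, pair_index: list[tuple[int, int]], n_taxa: int | None = None
) -> np.ndarray:
    """Per-taxon contribution ``psi(Y_i) = sum_{j != i} phi(P_ij)``."""
    pair_phi = np.asarray(pair_phi, dtype=float)
    if pair_phi.shape[0] != len(pair_index):
        raise ValueError("phi length does not match pair index")
    if n_taxa is None:
        n_taxa = max(max(i, j) for i, j in pair_index) + 1
    psi = np.zeros(n_taxa)
    for phi, (i, j) in zip(pair_phi, pair_index):
        psi[i] += phi
        psi[j] += phi
    return psi


def direction_of_effect(
    P: ProductMatrix, X: np.ndarray, C: np.ndarray | None = None
) -> np.ndarray:
    """Signed per-pair coefficient of the raw product on the scaled predictor.

    Each raw (pre-transform) product column is residualized on the
    covariates; ``beta_ij = x' P_ij_res / (x' x)``.  A positive value means
    the pair's co-abundance increases with the predictor.
    """
    x = _scale_vector(np.asarray(X, dtype=float).ravel(), "predictor")
    C_s, _ = _scale_covariates(C)
    P_res = residualize(P.values, C_s)
    x_res = residualize(x, C_s).ravel()
    return P_res.T @ x_res / float(x_res @ x_res)


def contribution_table(
    proj: PCProjection,
    betas: np.ndarray,
    P: ProductMatrix,
    X: np.ndarray,
    C: np.ndarray | None = None,
    predictor: str = "X",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-pair and per-taxon contribution tables.

    Returns ``(pairs, taxa)`` DataFrames: pairs carry phi and the direction
    sign; taxa carry psi.  Taxa are named when the projection knows its
    taxon ids, otherwise integer indices are used.
    """
    phi = pair_contributions(proj, betas)
    beta_ij = direction_of_effect(P, X, C)
    ids = proj.taxon_ids
    names = (lambda t: ids[t]) if ids else (lambda t: t)
    pairs = pd.DataFrame(
        {
            "taxon_i": [names(i) for i, _ in proj.pair_index],
            "taxon_j": [names(j) for _, j in proj.pair_index],
            "phi": phi,
            "beta": beta_ij,
            "sign": np.where(beta_ij >= 0, 1, -1),
            "predictor": predictor,
        }
    )
    n_taxa = len(ids) if ids else None
    psi = taxon_contributions(phi, proj.pair_index, n_taxa)
    taxa = pd.DataFrame(
        {
            "taxon": [names(t) for t in range(len(psi))],
            "psi": psi,
            "predictor": predictor,
        }
    )
    return pairs, taxa


def phi_permutation_null(
    proj: PCProjection,
    Q: np.ndarray,
    X: np.ndarray,
    C: np.ndarray | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null for the pair contributions (extension).

    The association chain defines no reference distribution for phi; this
    helper re-estimates the per-component coefficients after shuffling the
    predictor across samples and returns the ``n_permutations x M`` matrix
    of null phi values, against which observed weights can be ranked.
    """
    from .manocca import covariance_test

    rng = np.random.default_rng(seed)
    x = np.asarray(X, dtype=float).ravel()
    out = np.empty((n_permutations, proj.loadings.shape[0]))
    for b in range(n_permutations):
        perm = rng.permutation(x.shape[0])
        betas = covariance_test(Q, x[perm], None if C is None else np.asarray(C)[perm]).betas
        out[b] = pair_contributions(proj, betas)
    return out


def weight_vs_univariate_correlation(
    psi: np.ndarray, univariate_p: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of taxon weights with -log10 univariate p-values.

    Quantifies whether taxa contributing to the covariance signal also shift
    in mean abundance.  Returns ``(rho, p_value)``.
    """
    psi = np.asarray(psi, dtype=float)
    pv = np.asarray(univariate_p, dtype=float)
    if psi.shape[0] != pv.shape[0]:
        raise ValueError("mismatched taxa")
    if psi.shape[0] < 5:
        raise ValueError("need at least 5 taxa for a meaningful rank correlation")
    if np.all(psi == psi[0]) or np.all(pv == pv[0]):
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(psi, -np.log10(pv))
    return float(res.statistic), float(res.pvalue)
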