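"""Comparison methods run alongside the covariance-association test.

* MANOVA on arcsin-root transformed proportions (Wilks lambda, same shared
  single-predictor machinery as the covariance test);
* alpha diversity (Shannon and Simpson) regressed on the predictor;
* per-taxon univariate abundance regressions;
* a permutation-based network-difference approach for binary predictors,
  the threshold-style method the covariance test is designed to supersede.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._wilks import WilksTest, residualize, wilks_lambda_single
from .datatables import AbundanceTable
from .manocca import _scale_covariates, _scale_vector

__all__ = [
    "ManovaResult",
    "AlphaResult",
    "manova_test",
    "shannon_index",
    "simpson_index",
    "counts_from_relative",
    "alpha_regression",
    "alpha_diversity_test",
    "univariate_abundance_regression",
    "permutation_network",
]


@dataclass(frozen=True)
class ManovaResult:
    wilks: WilksTest

    @property
    def lambda_(self) -> float:
        return self.wilks.lambda_

    @property
    def p_value(self) -> float:
        return self.wilks.p_value


@dataclass
class AlphaResult:
    index_name: str
    alpha: np.ndarray
    coefficient: float
    p_value: float


def manova_test(
    Y: AbundanceTable | np.ndarray, X: np.ndarray, C: np.ndarray | None = None
) -> ManovaResult:
    """Wilks-lambda MANOVA of joint taxa abundance on a single predictor.

    Abundances are converted to per-sample proportions, entry-wise
    arcsin-root transformed, column-scaled, residualized on the covariates
    and tested with the exact one-predictor F transform.  Requires
    ``N > K + rank(C) + 1``; larger taxa sets must be reduced first.
    """
    vals = Y.values if isinstance(Y, AbundanceTable) else np.asarray(Y, dtype=float)
    n, k = vals.shape
    x = _scale_vector(np.asarray(X, dtype=float).ravel(), "predictor")
    C_s, c = _scale_covariates(C)
    if n <= k + c + 1:
        raise ValueError(
            f"N={n} too small for K={k} taxa with {c} covariate(s); "
            f"reduce the taxa dimension first"
        )
    totals = vals.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("sample with zero total abundance")
    props = vals / totals
    T = np.arcsin(np.sqrt(np.clip(props, 0.0, 1.0)))
    sds = T.std(axis=0)
    if (sds == 0).any():
        raise ValueError("constant taxon column after transformation")
    T = (T - T.mean(axis=0)) / sds
    Y_res = residualize(T, C_s)
    x_res = residualize(x, C_s).ravel()
    return ManovaResult(wilks=wilks_lambda_single(Y_res, x_res, n_covariates=c))


def shannon_index(x: np.ndarray) -> float:
    """Shannon entropy ``-sum p_i log p_i`` (natural log, zero counts drop out)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson_index(x: np.ndarray) -> float:
    """Unbiased (finite-sample) Simpson diversity on integer counts.

    ``1 - sum x_i (x_i - 1) / (T (T - 1))`` with ``T`` the total count;
    requires ``T >= 2``.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    if not np.allclose(x, np.round(x)):
        raise ValueError(
            "Simpson's finite-sample form needs integer counts; "
            "see counts_from_relative()"
        )
    total = x.sum()
    if total < 2:
        raise ValueError("total count must be >= 2")
    return float(1.0 - (x * (x - 1)).sum() / (total * (total - 1)))


def counts_from_relative(
    table: AbundanceTable, library_size: int = 10_000
) -> np.ndarray:
    """Reconstruct integer counts from relative abundances for Simpson's index."""
    return np.round(table.values * library_size)


def alpha_regression(
    alpha: np.ndarray, X: np.ndarray, C: np.ndarray | None = None
) -> tuple[float, float]:
    """OLS of a per-sample diversity value on predictor + covariates (Wald test)."""
    alpha = np.asarray(alpha, dtype=float)
    x = np.asarray(X, dtype=float).ravel()
    design = x[:, None]
    if C is not None and np.size(C) > 0:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        design = np.hstack([design, C])
    design = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")
    fit = sm.OLS(alpha, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def alpha_diversity_test(
    Y: AbundanceTable,
    X: np.ndarray,
    C: np.ndarray | None = None,
    index: str = "shannon",
    library_size: int = 10_000,
) -> AlphaResult:
    """Per-sample alpha diversity regressed on the predictor."""
    if index == "shannon":
        alpha = np.array([shannon_index(row) for row in Y.values])
    elif index == "simpson":
        counts = counts_from_relative(Y, library_size)
        alpha = np.array([simpson_index(row) for row in counts])
    else:
        raise ValueError(f"unknown index {index!r}")
    coef, p = alpha_regression(alpha, X, C)
    return AlphaResult(index_name=index, alpha=alpha, coefficient=coef, p_value=p)


def univariate_abundance_regression(
    Y: AbundanceTable | np.ndarray,
    X: np.ndarray,
    C: np.ndarray | None = None,
    pre_int: bool = True,
) -> pd.DataFrame:
    """Per-taxon OLS ``abundance ~ X + C`` with Wald p-values on X.

    With ``pre_int`` (default) each taxon is inverse-normal transformed
    first, matching the scale the covariance chain analyses; raw relative
    abundances of rare taxa are so heavy-tailed that a linear fit on them
    has little power.  Constant taxa are skipped with a warning (p = NaN).
    The returned frame carries the Bonferroni threshold ``0.05 / K`` in
    ``attrs`` and is the mean-effect counterpart to the covariance
    contributions.
    """
    if isinstance(Y, AbundanceTable):
        vals, taxa = Y.values, Y.taxon_ids
    else:
        vals = np.asarray(Y, dtype=float)
        taxa = list(range(vals.shape[1]))
    if pre_int:
        from .manocca import inverse_normal_transform

        vals = np.column_stack(
            [
                inverse_normal_transform(vals[:, j])
                if vals[:, j].std() > 0
                else vals[:, j]
                for j in range(vals.shape[1])
            ]
        )
    x = np.asarray(X, dtype=float).ravel()
    design = x[:, None]
    if C is not None and np.size(C) > 0:
        Cm = np.asarray(C, dtype=float)
        if Cm.ndim == 1:
            Cm = Cm[:, None]
        design = np.hstack([design, Cm])
    design = sm.add_constant(design, has_constant="add")
    rows = []
    for j, taxon in enumerate(taxa):
        col = vals[:, j]
        if col.std() == 0:
            warnings.warn(f"skipping constant taxon {taxon!r}", stacklevel=2)
            rows.append({"taxon": taxon, "beta": np.nan, "p_value": np.nan})
            continue
        fit = sm.OLS(col, design).fit()
        rows.append(
            {"taxon": taxon, "beta": float(fit.params[1]),
             "p_value": float(fit.pvalues[1])}
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni"] = 0.05 / len(taxa)
    return out


def permutation_network(
    Y: AbundanceTable | np.ndarray,
    X: np.ndarray,
    n_permutations: int = 1000,
    detection_quantile: float = 0.95,
    seed: int = 0,
) -> dict:
    """Threshold-based network difference between the two levels of a binary predictor.

    Within each group the sample covariance of every taxa pair is compared
    with an empirical two-sided null built by shuffling one member taxon
    across the group's individuals ``n_permutations`` times; a pair is
    detected when ``|cov|`` exceeds the ``detection_quantile`` of its null
    magnitudes.  Pairs detected in exactly one group are reported as the
    co-abundance differences between conditions.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations for stable quantiles")
    if not 0 < detection_quantile < 1:
        raise ValueError("detection_quantile must be in (0, 1)")
    vals = Y.values if isinstance(Y, AbundanceTable) else np.asarray(Y, dtype=float)
    taxa = Y.taxon_ids if isinstance(Y, AbundanceTable) else list(range(vals.shape[1]))
    x = np.asarray(X, dtype=float).ravel()
    levels = np.unique(x)
    if len(levels) != 2:
        raise ValueError(f"predictor must be binary, found {len(levels)} levels")
    rng = np.random.default_rng(seed)
    k = vals.shape[1]
    iu, ju = np.triu_indices(k, k=1)
    detected: dict[float, set] = {}
    covariances: dict[float, np.ndarray] = {}
    for level in levels:
        sub = vals[x == level]
        ng = sub.shape[0]
        if ng < 20:
            raise ValueError(f"group {level} has only {ng} samples (need >= 20)")
        centered = sub - sub.mean(axis=0)
        cov = centered.T @ centered / (ng - 1)
        # null: covariance of taxon i with an independently shuffled taxon j
        null_abs = np.empty((n_permutations, k, k))
        for b in range(n_permutations):
            perm = np.empty_like(centered)
            for j in range(k):
                perm[:, j] = centered[rng.permutation(ng), j]
            null_abs[b] = np.abs(centered.T @ perm / (ng - 1))
        thresh = np.quantile(null_abs, detection_quantile, axis=0)
        hits = np.abs(cov) > thresh
        detected[level] = {
            (taxa[i], taxa[j]) for i, j in zip(iu, ju) if hits[i, j]
        }
        covariances[level] = cov
    a, b = levels
    return {
        "levels": (a, b),
        "detected": detected,
        "unique": {
            a: detected[a] - detected[b],
            b: detected[b] - detected[a],
        },
        "covariances": covariances,
    }
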