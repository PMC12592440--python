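"""Covariance-based prediction of host features from taxa products.

A training split runs the product chain (standardize, pairwise products,
inverse-normal transform, PCA) and regresses the outcome on the leading L
components; the score of a new sample is the trained coefficient sum
``S = sum_i beta_i PC_i`` where the test components are obtained by
replaying every train-fitted transform — taxa scalers, per-product
empirical quantile maps, centering offsets and loadings — never by
refitting on test data.  A like-for-like mean-abundance baseline uses OLS
on the leading L principal components of the (standardized) abundance
matrix itself.  Accuracy is squared Pearson correlation for continuous
outcomes and the Mann-Whitney AUC for binary ones, over repeated random
90/10 splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatables import AbundanceTable
from .manocca import pairwise_products, transform_products

__all__ = [
    "CovPredictor",
    "MeanPredictor",
    "CVReport",
    "fit_cov_predictor",
    "predict_cov",
    "fit_mean_predictor",
    "predict_mean",
    "cross_validate",
    "r_squared",
    "auc",
]


@dataclass
class CovPredictor:
    """Train-fitted covariance prediction model (all transforms frozen).

    ``taxa_quantile_maps`` replay the optional per-taxon rank-normalization
    on held-out samples; ``quantile_maps`` do the same for the per-product
    inverse-normal step.
    """

    taxon_ids: list
    taxa_means: np.ndarray
    taxa_sds: np.ndarray
    quantile_maps: list[tuple[np.ndarray, np.ndarray]]
    product_means: np.ndarray
    loadings: np.ndarray  # M x L
    intercept: float
    betas: np.ndarray  # length L
    L: int
    taxa_quantile_maps: list[tuple[np.ndarray, np.ndarray]] | None = None


@dataclass
class MeanPredictor:
    """Abundance-PC baseline model (same projection discipline)."""

    taxon_ids: list
    taxa_means: np.ndarray
    taxa_sds: np.ndarray
    loadings: np.ndarray  # K x L
    intercept: float
    betas: np.ndarray
    L: int


@dataclass
class CVReport:
    """Per-split accuracies of the two models and their comparison."""

    metric: str
    cov_scores: np.ndarray
    mean_scores: np.ndarray
    splits: list[tuple[np.ndarray, np.ndarray]]
    t_statistic: float
    p_value: float
    redrawn: int = 0
    extras: dict = field(default_factory=dict)


def _standardize_train(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = vals.mean(axis=0)
    sds = vals.std(axis=0)
    if (sds == 0).any():
        raise ValueError("zero-variance taxon in training data")
    return (vals - means) / sds, means, sds


def fit_cov_predictor(
    Y_train: AbundanceTable | np.ndarray,
    A_train: np.ndarray,
    L: int,
    pre_int: bool = True,
) -> CovPredictor:
    """Fit the covariance model: product chain then OLS of A on L components."""
    vals, taxa = _table_values(Y_train)
    A = np.asarray(A_train, dtype=float).ravel()
    n = vals.shape[0]
    if L < 1:
        raise ValueError("L must be >= 1")
    if L >= n - 1:
        raise ValueError(f"L={L} >= N_train - 1 = {n - 1}")
    if np.isnan(A).any():
        raise ValueError("training outcome contains missing values")
    taxa_maps = None
    if pre_int:
        from .manocca import inverse_normal_transform

        taxa_maps = []
        ranked = np.empty_like(vals)
        for j in range(vals.shape[1]):
            ranked[:, j] = inverse_normal_transform(vals[:, j])
            xs, idx = np.unique(vals[:, j], return_index=True)
            taxa_maps.append((xs, ranked[idx, j].copy()))
        vals = ranked
    Z, means, sds = _standardize_train(vals)
    P = pairwise_products(Z, taxa)
    P_int, maps = transform_products(P, keep_quantile_maps=True)
    pmeans = P_int.values.mean(axis=0)
    centered = P_int.values - pmeans
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    loadings = Vt[:L].T
    scores = centered @ loadings
    design = np.hstack([np.ones((n, 1)), scores])
    coef, *_ = np.linalg.lstsq(design, A, rcond=None)
    return CovPredictor(
        taxon_ids=list(taxa) if taxa is not None else list(range(vals.shape[1])),
        taxa_means=means,
        taxa_sds=sds,
        quantile_maps=maps,
        product_means=pmeans,
        loadings=loadings,
        intercept=float(coef[0]),
        betas=coef[1:],
        L=L,
        taxa_quantile_maps=taxa_maps,
    )


def predict_cov(model: CovPredictor, Y_test: AbundanceTable | np.ndarray) -> np.ndarray:
    """Score held-out samples with the frozen train transforms.

    Taxa are (optionally) mapped through the train rank-normalization
    quantile maps, standardized with the train scalers; products are mapped
    through the train empirical quantile functions (linear interpolation,
    clipped at the train extremes), centered with the train product means
    and projected on the train loadings; no transform is re-estimated.
    """
    vals, taxa = _table_values(Y_test)
    _check_taxa(model.taxon_ids, taxa, vals.shape[1])
    if model.taxa_quantile_maps is not None:
        mapped_taxa = np.empty_like(vals)
        for j, (xs, ys) in enumerate(model.taxa_quantile_maps):
            mapped_taxa[:, j] = np.interp(vals[:, j], xs, ys)
        vals = mapped_taxa
    Z = (vals - model.taxa_means) / model.taxa_sds
    P = pairwise_products(Z)
    mapped = np.empty_like(P.values)
    for j, (xs, ys) in enumerate(model.quantile_maps):
        mapped[:, j] = np.interp(P.values[:, j], xs, ys)
    scores = (mapped - model.product_means) @ model.loadings
    return model.intercept + scores @ model.betas


def fit_mean_predictor(
    Y_train: AbundanceTable | np.ndarray, A_train: np.ndarray, L: int
) -> MeanPredictor:
    """Abundance baseline: OLS of A on the leading L abundance PCs."""
    vals, taxa = _table_values(Y_train)
    A = np.asarray(A_train, dtype=float).ravel()
    n, k = vals.shape
    if L < 1:
        raise ValueError("L must be >= 1")
    L_eff = min(L, k, n - 2)
    Z, means, sds = _standardize_train(vals)
    Zc = Z - Z.mean(axis=0)  # already centered; keep explicit
    _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
    loadings = Vt[:L_eff].T
    scores = Zc @ loadings
    design = np.hstack([np.ones((n, 1)), scores])
    coef, *_ = np.linalg.lstsq(design, A, rcond=None)
    return MeanPredictor(
        taxon_ids=list(taxa) if taxa is not None else list(range(k)),
        taxa_means=means,
        taxa_sds=sds,
        loadings=loadings,
        intercept=float(coef[0]),
        betas=coef[1:],
        L=L_eff,
    )


def predict_mean(model: MeanPredictor, Y_test: AbundanceTable | np.ndarray) -> np.ndarray:
    vals, taxa = _table_values(Y_test)
    _check_taxa(model.taxon_ids, taxa, vals.shape[1])
    Z = (vals - model.taxa_means) / model.taxa_sds
    scores = Z @ model.loadings
    return model.intercept + scores @ model.betas


def cross_validate(
    Y: AbundanceTable | np.ndarray,
    A: np.ndarray,
    n_splits: int = 30,
    test_fraction: float = 0.1,
    metric: str = "r2",
    L: int = 100,
    seed: int = 0,
) -> CVReport:
    """Repeated random 90/10 split comparison of the two models.

    Each of ``n_splits`` splits holds out ``test_fraction`` of the samples,
    fits both models on the rest and evaluates the chosen metric on the
    held-out scores; the two per-split metric vectors are compared with a
    two-sample two-sided t-test.  Binary outcomes redraw any split whose
    test part is single-class (logged in the report).
    """
    vals, taxa = _table_values(Y)
    A = np.asarray(A, dtype=float).ravel()
    n = vals.shape[0]
    n_test = int(round(test_fraction * n))
    if n_test < 10:
        raise ValueError(f"test split of {n_test} samples is too small (need >= 10)")
    if metric not in ("r2", "auc"):
        raise ValueError("metric must be 'r2' or 'auc'")
    rng = np.random.default_rng(seed)
    L_fit = min(L, n - n_test - 2)
    cov_scores = np.empty(n_splits)
    mean_scores = np.empty(n_splits)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    redrawn = 0
    for s in range(n_splits):
        while True:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if metric == "auc" and len(np.unique(A[test_idx])) < 2:
                redrawn += 1
                continue
            break
        splits.append((train_idx, test_idx))
        Ytr, Yte = vals[train_idx], vals[test_idx]
        cov_model = fit_cov_predictor(Ytr, A[train_idx], L_fit)
        mean_model = fit_mean_predictor(Ytr, A[train_idx], L_fit)
        s_cov = predict_cov(cov_model, Yte)
        s_mean = predict_mean(mean_model, Yte)
        score = r_squared if metric == "r2" else auc
        cov_scores[s] = score(s_cov, A[test_idx])
        mean_scores[s] = score(s_mean, A[test_idx])
    if np.array_equal(cov_scores, mean_scores):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(cov_scores, mean_scores)
    return CVReport(
        metric=metric,
        cov_scores=cov_scores,
        mean_scores=mean_scores,
        splits=splits,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        redrawn=redrawn,
    )


def r_squared(S: np.ndarray, A: np.ndarray) -> float:
    """Squared Pearson correlation ``cor(S, A)^2``."""
    S = np.asarray(S, dtype=float).ravel()
    A = np.asarray(A, dtype=float).ravel()
    if S.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if S.std() == 0:
        warnings.warn("zero-variance scores; r^2 set to 0", stacklevel=2)
        return 0.0
    if A.std() == 0:
        raise ValueError("constant outcome")
    return float(np.corrcoef(S, A)[0, 1] ** 2)


def auc(S: np.ndarray, A: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score of random positive > random negative), ties 1/2."""
    S = np.asarray(S, dtype=float).ravel()
    A = np.asarray(A, dtype=float).ravel()
    classes = np.unique(A)
    if len(classes) != 2:
        raise ValueError("AUC needs exactly two outcome classes")
    pos = A == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(S)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _table_values(Y) -> tuple[np.ndarray, list | None]:
    if isinstance(Y, AbundanceTable):
        return Y.values, Y.taxon_ids
    return np.asarray(Y, dtype=float), None


def _check_taxa(train_taxa: list, test_taxa: list | None, k_test: int) -> None:
    if test_taxa is None:
        if k_test != len(train_taxa):
            raise ValueError(
                f"test data has {k_test} taxa, model expects {len(train_taxa)}"
            )
        return
    if list(test_taxa) != list(train_taxa):
        extra = sorted(set(test_taxa) - set(train_taxa))
        miss = sorted(set(train_taxa) - set(test_taxa))
        raise ValueError(
            f"taxa mismatch between train and test: missing={miss}, extra={extra}"
        )
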