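"""Synthetic compositional microbiome data with predictor-driven covariance.

The generator emulates the statistical structure of a prevalence-filtered
relative-abundance table: sparse, heavy-tailed compositions whose pairwise
covariance (and, optionally, mean) is modulated by a host predictor, plus a
correlated nuisance covariate.  The generative path is:

* two endpoint correlation matrices Sigma_A / Sigma_B that differ by
  ``+/- delta`` on a chosen set of taxa pairs;
* each individual draws a latent Gaussian vector with covariance on the
  convex path ``(1 - w_i) Sigma_A + w_i Sigma_B`` where ``w_i`` is a
  logistic weight of a continuous predictor, or the group label of a binary
  one (convexity keeps every per-individual covariance valid);
* per-taxon log-normal abundances spanning ~3 decades of mean abundance;
* independent zero-inflation followed by re-closure of each sample to 1.

The modulated pairs and any mean-shifted taxa are recorded as ground truth
so downstream power, calibration and recovery properties are testable
without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatables import (
    AbundanceTable,
    FeatureTable,
    TaxonomyMap,
    write_abundance_table,
    write_feature_table,
    write_taxonomy,
)

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "make_endpoint_correlations",
    "simulate_dataset",
    "write_dataset",
]

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort.

    Defaults describe a moderate screening scenario: 600 samples, 30 taxa in
    10 families, a continuous predictor shifting 20 pairwise correlations by
    0.6, 20% zero-inflation, and one covariate correlated 0.3 with the
    predictor.  ``mean_effect`` is the per-unit-predictor shift of the
    log-scale mean of ``n_mean_taxa`` designated taxa (0 disables it).
    """

    n_samples: int = 600
    n_taxa: int = 30
    n_families: int = 10
    predictor_kind: str = "continuous"  # or "binary"
    covariance_effect: float = 0.6
    mean_effect: float = 0.0
    n_modulated_pairs: int = 20
    n_mean_taxa: int = 5
    sparsity: float = 0.2
    covariate_correlation: float = 0.3
    log_mean_decades: float = 3.0
    log_sd: float = 1.0
    mean_taxa_mode: str = "first"  # or "rarest"
    seed: int = 0

    def __post_init__(self) -> None:
        max_pairs = self.n_taxa * (self.n_taxa - 1) // 2
        if self.n_modulated_pairs > max_pairs:
            raise ValueError(
                f"n_modulated_pairs={self.n_modulated_pairs} exceeds "
                f"K(K-1)/2={max_pairs}"
            )
        if not np.isfinite(self.covariance_effect) or not np.isfinite(self.mean_effect):
            raise ValueError("effect sizes must be finite")
        if self.covariance_effect < 0:
            raise ValueError("covariance_effect must be >= 0")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if not -1 < self.covariate_correlation < 1:
            raise ValueError("covariate_correlation must be in (-1, 1)")
        if self.predictor_kind not in ("continuous", "binary"):
            raise ValueError("predictor_kind must be 'continuous' or 'binary'")
        if self.mean_taxa_mode not in ("first", "rarest"):
            raise ValueError("mean_taxa_mode must be 'first' or 'rarest'")


@dataclass
class SimulatedDataset:
    """A simulated cohort plus its generative ground truth."""

    abundance: AbundanceTable
    taxonomy: TaxonomyMap
    features: FeatureTable
    truth_pairs: list[tuple[int, int]]
    truth_signs: list[int]
    mean_taxa: list[int] = field(default_factory=list)
    spec: SimulationSpec | None = None

    @property
    def truth_pair_ids(self) -> list[tuple[str, str]]:
        taxa = self.abundance.taxon_ids
        return [(taxa[i], taxa[j]) for i, j in self.truth_pairs]


def make_endpoint_correlations(
    n_taxa: int,
    n_modulated_pairs: int,
    delta: float,
    seed: int,
    signs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Build the two endpoint correlation matrices differing on chosen pairs.

    Sigma_A is the identity; Sigma_B adds ``sign * delta`` to
    ``n_modulated_pairs`` randomly chosen off-diagonal entries
    (symmetrically).  If the perturbed matrix is not positive semi-definite
    it is repaired by eigenvalue clipping followed by re-normalization to
    unit diagonal; when the repair erodes any modulated entry below
    ``delta / 2`` the requested effect is declared infeasible.
    """
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    if n_modulated_pairs > len(all_pairs):
        raise ValueError("more modulated pairs than available pairs")
    chosen = rng.choice(len(all_pairs), size=n_modulated_pairs, replace=False)
    pairs = sorted(all_pairs[c] for c in chosen)
    if signs is None:
        signs = np.ones(n_modulated_pairs)
    sigma_a = np.eye(n_taxa)
    sigma_b = np.eye(n_taxa)
    for (i, j), s in zip(pairs, signs):
        sigma_b[i, j] = sigma_b[j, i] = s * delta
    sigma_b = _nearest_unit_diagonal_psd(sigma_b)
    if delta > 0:
        achieved = np.array([abs(sigma_b[i, j]) for i, j in pairs])
        if (achieved < delta / 2).any():
            raise ValueError(
                f"delta={delta} infeasible: PSD repair reduced some modulated "
                f"correlations below {delta / 2} (min achieved {achieved.min():.3f})"
            )
    return sigma_a, sigma_b, pairs


def _nearest_unit_diagonal_psd(S: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, V = np.linalg.eigh(S)
    if w.min() >= -_PSD_TOL:
        return S
    w = np.clip(w, 0.0, None)
    R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one cohort according to ``spec``; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_taxa
    sigma_a, sigma_b, pairs = make_endpoint_correlations(
        k, spec.n_modulated_pairs, spec.covariance_effect, seed=int(rng.integers(2**31))
    )
    signs = [int(np.sign(sigma_b[i, j])) if sigma_b[i, j] != 0 else 1 for i, j in pairs]

    if spec.predictor_kind == "binary":
        x = rng.binomial(1, 0.5, size=n).astype(float)
        w = x
    else:
        x = rng.standard_normal(n)
        w = 1.0 / (1.0 + np.exp(-x))

    z = _sample_latent(rng, sigma_a, sigma_b, w)

    # per-taxon log-scale means spanning ~`log_mean_decades` orders of magnitude
    mu = rng.uniform(-spec.log_mean_decades * np.log(10), 0.0, size=k)
    # "rarest" designates the lowest-abundance taxa: their compositional
    # feedback through the per-sample total is negligible, so the shift
    # stays a pure mean effect instead of leaking into re-closure covariance
    if spec.mean_effect == 0:
        mean_taxa: list[int] = []
    elif spec.mean_taxa_mode == "rarest":
        mean_taxa = np.argsort(mu)[: spec.n_mean_taxa].tolist()
    else:
        mean_taxa = list(range(spec.n_mean_taxa))
    log_abund = mu[None, :] + spec.log_sd * z
    if mean_taxa:
        log_abund[:, mean_taxa] += spec.mean_effect * x[:, None]
    abund = np.exp(log_abund)

    if spec.sparsity > 0:
        mask = rng.random((n, k)) < spec.sparsity
        # keep each sample non-empty: never zero out its largest entry
        argmax = abund.argmax(axis=1)
        mask[np.arange(n), argmax] = False
        abund[mask] = 0.0
    abund /= abund.sum(axis=1, keepdims=True)

    taxa = [f"g{t:03d}" for t in range(k)]
    families = [f"f{t % spec.n_families:02d}" for t in range(k)]
    taxonomy = TaxonomyMap(
        pd.DataFrame({"genus": taxa, "family": families}).set_index(
            pd.Index(taxa, name="taxon_id")
        )
    )
    samples = [f"s{i:04d}" for i in range(n)]
    abundance = AbundanceTable(
        pd.DataFrame(abund, index=samples, columns=taxa), rank="genus"
    )

    rho = spec.covariate_correlation
    x_std = (x - x.mean()) / x.std()
    covariate = rho * x_std + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    features = FeatureTable(
        pd.DataFrame({"predictor": x, "covariate": covariate}, index=samples),
        {
            "predictor": "binary" if spec.predictor_kind == "binary" else "continuous",
            "covariate": "continuous",
        },
    )
    return SimulatedDataset(
        abundance=abundance,
        taxonomy=taxonomy,
        features=features,
        truth_pairs=pairs,
        truth_signs=signs,
        mean_taxa=mean_taxa,
        spec=spec,
    )


def _sample_latent(
    rng: np.random.Generator,
    sigma_a: np.ndarray,
    sigma_b: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    """Latent Gaussians with per-individual covariance on the convex path."""
    n = w.shape[0]
    k = sigma_a.shape[0]
    eps = rng.standard_normal((n, k))
    z = np.empty((n, k))
    # group identical weights (binary predictors) to reuse Cholesky factors
    uniq, inv = np.unique(w, return_inverse=True)
    if len(uniq) <= 8:
        for g, wg in enumerate(uniq):
            cov = (1 - wg) * sigma_a + wg * sigma_b
            _check_psd(cov)
            L = _safe_cholesky(cov)
            rows = inv == g
            z[rows] = eps[rows] @ L.T
    else:
        for i in range(n):
            cov = (1 - w[i]) * sigma_a + w[i] * sigma_b
            L = _safe_cholesky(cov)
            z[i] = L @ eps[i]
    return z


def _check_psd(cov: np.ndarray) -> None:
    wmin = float(np.linalg.eigvalsh(cov).min())
    if wmin < -_PSD_TOL:
        raise ValueError(f"per-individual covariance not PSD (min eig {wmin:.2e})")


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # PSD but numerically semi-definite: jitter the diagonal
        return np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three analysis TSVs plus the ground-truth pair table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "features": out / "features.tsv",
        "feature_types": out / "feature_types.tsv",
        "truth": out / "truth_pairs.tsv",
    }
    write_abundance_table(dataset.abundance, paths["abundance"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    write_feature_table(dataset.features, paths["features"], paths["feature_types"])
    spec = dataset.spec
    truth = pd.DataFrame(
        {
            "taxon_i": [a for a, _ in dataset.truth_pair_ids],
            "taxon_j": [b for _, b in dataset.truth_pair_ids],
            "delta": spec.covariance_effect if spec else np.nan,
            "sign": dataset.truth_signs,
        }
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
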