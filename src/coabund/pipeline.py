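"""End-to-end orchestration: simulate -> QC -> screen -> contributions ->
network -> baselines -> predict, with one global seed and a manifest.

All stage randomness is derived from the config's global seed through named
substreams, so re-running any single stage reproduces the run.  Outputs are
TSV (GraphML for networks) plus a JSON manifest recording versions, the
config hash and per-stage runtimes.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import (
    alpha_diversity_test,
    manova_test,
    permutation_network,
    univariate_abundance_regression,
)
from .contributions import contribution_table
from .datatables import (
    AbundanceTable,
    FeatureTable,
    TaxonomyMap,
    aggregate_to_rank,
    filter_taxa_by_prevalence,
    intersect_samples,
    qc_features,
    read_abundance_table,
    read_feature_table,
    read_taxonomy,
)
from .manocca import (
    manocca_scan,
    multiple_testing_thresholds,
    pairwise_products,
    standardize_columns,
)
from .network import build_network, export_graphml, overlap_counts, top_pairs
from .prediction import cross_validate
from .simulate import SimulationSpec, simulate_dataset, write_dataset

__all__ = ["AnalysisConfig", "substream_seed", "run_screen", "run_full_pipeline"]

DEFAULT_PREVALENCE = {"species": 0.40, "genus": 0.05, "family": 0.05}


@dataclass
class AnalysisConfig:
    """Plain-text configuration of one pipeline run."""

    abundance_path: str | None = None
    taxonomy_path: str | None = None
    features_path: str | None = None
    feature_types_path: str | None = None
    rank: str = "genus"
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    predictors: list[str] = field(default_factory=lambda: ["predictor"])
    covariates: list[str] = field(default_factory=lambda: ["covariate"])
    pc_grid: str = "2:100"
    max_missing_frac: float = 0.5
    min_binary_freq: float = 0.05
    outlier_sd: float = 3.0
    n_permutations: int = 1000
    detection_quantile: float = 0.95
    top_k_pairs: int = 1000
    cv_splits: int = 30
    cv_test_fraction: float = 0.1
    cv_components: int = 100
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def grid(self) -> list[int]:
        lo, hi = (int(v) for v in self.pc_grid.split(":"))
        return list(range(lo, hi + 1))


def substream_seed(seed: int, name: str) -> int:
    """Stable per-stage seed (< 2**31) derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_tables(
    config: AnalysisConfig,
) -> tuple[AbundanceTable, TaxonomyMap, FeatureTable]:
    if not (config.abundance_path and config.taxonomy_path and config.features_path):
        raise ValueError("config must provide abundance, taxonomy and feature paths")
    abundance = read_abundance_table(config.abundance_path, rank=config.rank)
    taxonomy = read_taxonomy(config.taxonomy_path)
    features = read_feature_table(config.features_path, config.feature_types_path)
    return abundance, taxonomy, features


def prepare_abundance(
    abundance: AbundanceTable, taxonomy: TaxonomyMap, config: AnalysisConfig
) -> AbundanceTable:
    """Aggregate to the configured rank and apply its prevalence filter."""
    table = aggregate_to_rank(abundance, taxonomy, config.rank)
    threshold = config.prevalence.get(config.rank, 0.05)
    return filter_taxa_by_prevalence(table, threshold)


def run_screen(
    abundance: AbundanceTable,
    features: FeatureTable,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, dict]:
    """One covariance-association scan per predictor at the configured rank.

    A predictor is excluded from its own covariate set.  Rows are sorted by
    p-value; threshold flags use the Bonferroni pair for the number of
    predictors and component models screened.
    """
    if not config.predictors:
        raise ValueError("empty predictor list")
    grid = config.grid()
    stringent, suggestive = multiple_testing_thresholds(
        len(config.predictors), len(grid)
    )
    abundance, features = intersect_samples(abundance, features)
    rows = []
    results = {}
    for predictor in config.predictors:
        covs = [c for c in config.covariates if c != predictor]
        cols = [predictor] + covs
        sub = features.data[cols].dropna()
        if len(sub) < 10:
            raise ValueError(
                f"screen[{predictor}]: only {len(sub)} complete cases"
            )
        idx = sub.index
        Y = AbundanceTable(abundance.data.loc[idx], rank=abundance.rank)
        X = sub[predictor].to_numpy()
        C = sub[covs].to_numpy() if covs else None
        try:
            res = manocca_scan(Y, X, C, p_grid=grid, predictor=predictor)
        except Exception as exc:
            raise RuntimeError(f"screen[{predictor}] failed: {exc}") from exc
        results[predictor] = (res, Y, X, C)
        rows.append(
            {
                "predictor": predictor,
                "rank": abundance.rank,
                "optimal_p": res.optimal_p,
                "p_value": res.p_value,
                "n": res.n_samples,
                "passes_stringent": res.p_value < stringent,
                "passes_suggestive": res.p_value < suggestive,
            }
        )
    table = pd.DataFrame(rows).sort_values("p_value", kind="mergesort").reset_index(
        drop=True
    )
    table.attrs["stringent"] = stringent
    table.attrs["suggestive"] = suggestive
    return table, results


def run_full_pipeline(config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write a results directory with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    timings = manifest["stages"]

    def stage(name):
        t0 = time.perf_counter()
        return lambda: timings.__setitem__(name, round(time.perf_counter() - t0, 3))

    # --- simulate or load -------------------------------------------------
    done = stage("simulate")
    if config.abundance_path:
        abundance, taxonomy, features = load_tables(config)
        truth = None
    else:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", substream_seed(config.seed, "simulate"))
        spec = SimulationSpec(**sim_kwargs)
        dataset = simulate_dataset(spec)
        write_dataset(dataset, out / "simulated")
        abundance, taxonomy, features = (
            dataset.abundance,
            dataset.taxonomy,
            dataset.features,
        )
        truth = dataset.truth_pair_ids
    done()

    # --- QC ---------------------------------------------------------------
    done = stage("qc")
    abundance = prepare_abundance(abundance, taxonomy, config)
    features, qc_report = qc_features(
        features,
        max_missing_frac=config.max_missing_frac,
        min_binary_freq=config.min_binary_freq,
        outlier_sd=config.outlier_sd,
    )
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    done()

    # --- screen -----------------------------------------------------------
    done = stage("screen")
    screen_table, scan_results = run_screen(abundance, features, config)
    screen_table.to_csv(out / "screen.tsv", sep="\t", index=False)
    done()

    # --- contributions + network -----------------------------------------
    done = stage("contrib")
    edge_lists = {}
    for predictor, (res, Y, X, C) in scan_results.items():
        Z = standardize_columns(Y.values, Y.taxon_ids)
        P = pairwise_products(Z, Y.taxon_ids)
        pairs, taxa = contribution_table(
            res.projection, res.betas, P, X, C, predictor=predictor
        )
        pairs.to_csv(out / f"contrib_pairs_{predictor}.tsv", sep="\t", index=False)
        taxa.to_csv(out / f"contrib_taxa_{predictor}.tsv", sep="\t", index=False)
        k = min(config.top_k_pairs, len(pairs))
        edge_lists[predictor] = top_pairs(pairs, k=k)
    done()

    done = stage("network")
    G = build_network(edge_lists)
    export_graphml(G, out / "network.graphml")
    edge_rows = pd.concat(
        [df.assign(predictor=p) for p, df in edge_lists.items()], ignore_index=True
    )
    edge_rows.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    if len(edge_lists) >= 2:
        cells = overlap_counts(
            {
                p: {(r.taxon_i, r.taxon_j) for r in df.itertuples()}
                for p, df in edge_lists.items()
            }
        )
        pd.DataFrame(
            [{"cell": "+".join(sorted(c)), "count": n} for c, n in cells.items()]
        ).to_csv(out / "venn_pairs.tsv", sep="\t", index=False)
    done()

    # --- baselines --------------------------------------------------------
    done = stage("baselines")
    base_rows = []
    perm_seed = substream_seed(config.seed, "permute")
    for predictor, (res, Y, X, C) in scan_results.items():
        try:
            man = manova_test(Y, X, C)
            base_rows.append(
                {"predictor": predictor, "method": "manova", "p_value": man.p_value}
            )
        except ValueError as exc:
            warnings.warn(f"manova[{predictor}] skipped: {exc}", stacklevel=2)
        for index in ("shannon", "simpson"):
            ares = alpha_diversity_test(Y, X, C, index=index)
            base_rows.append(
                {"predictor": predictor, "method": index, "p_value": ares.p_value}
            )
        uni = univariate_abundance_regression(Y, X, C)
        uni.to_csv(out / f"univariate_{predictor}.tsv", sep="\t", index=False)
        if len(np.unique(X)) == 2 and min(np.bincount((X == np.max(X)).astype(int))) >= 20:
            pn = permutation_network(
                Y, X, n_permutations=config.n_permutations,
                detection_quantile=config.detection_quantile, seed=perm_seed,
            )
            for level, uniq in pn["unique"].items():
                base_rows.append(
                    {"predictor": predictor,
                     "method": f"permnet_unique_level_{level:g}",
                     "p_value": np.nan, "n_pairs": len(uniq)}
                )
    pd.DataFrame(base_rows).to_csv(out / "baselines.tsv", sep="\t", index=False)
    done()

    # --- prediction -------------------------------------------------------
    done = stage("predict")
    pred_rows = []
    cv_seed = substream_seed(config.seed, "cv")
    for predictor, (res, Y, X, C) in scan_results.items():
        metric = "auc" if len(np.unique(X)) == 2 else "r2"
        report = cross_validate(
            Y, X, n_splits=config.cv_splits,
            test_fraction=config.cv_test_fraction, metric=metric,
            L=config.cv_components, seed=cv_seed,
        )
        pred_rows.append(
            {
                "predictor": predictor,
                "metric": metric,
                "cov_median": float(np.median(report.cov_scores)),
                "mean_median": float(np.median(report.mean_scores)),
                "t_statistic": report.t_statistic,
                "p_value": report.p_value,
            }
        )
        per_split = pd.DataFrame(
            {
                "split": range(config.cv_splits),
                "covariance_model": report.cov_scores,
                "mean_model": report.mean_scores,
            }
        )
        per_split.to_csv(out / f"cv_{predictor}.tsv", sep="\t", index=False)
    pd.DataFrame(pred_rows).to_csv(out / "prediction.tsv", sep="\t", index=False)
    done()

    if truth is not None:
        manifest["truth_pairs"] = [list(t) for t in truth]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
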