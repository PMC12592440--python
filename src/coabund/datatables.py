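"""Core tabular containers and their quality-control operations.

Three tables drive every analysis in this package:

* :class:`AbundanceTable` — samples x taxa relative abundances at one
  taxonomic rank.  Zeros encode absence; missing cells are not allowed.
* :class:`TaxonomyMap` — per-taxon lineage used to aggregate abundances to
  a coarser rank by summing descendants.
* :class:`FeatureTable` — samples x host features (continuous, binary or
  categorical) with explicit missingness.

All on-disk formats are plain TSV (UTF-8, '.' decimal separator, "NA" as the
missing marker for features), readable with any spreadsheet or R session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TaxonomyMap",
    "FeatureTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_feature_table",
    "write_feature_table",
    "aggregate_to_rank",
    "filter_taxa_by_prevalence",
    "qc_features",
    "intersect_samples",
]

FEATURE_TYPES = ("continuous", "binary", "categorical")


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of non-negative relative abundances.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and taxon ids as columns.
    rank:
        Taxonomic rank label of the columns (e.g. ``"genus"``).
    """

    data: pd.DataFrame
    rank: str = "taxon"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicated taxon ids: {dup}")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = map(int, np.argwhere(np.isnan(vals))[0])
            raise ValueError(
                f"missing abundance at sample {df.index[r]!r}, taxon "
                f"{df.columns[c]!r}: zeros encode absence, NaN is not allowed"
            )
        if (vals < 0).any():
            r, c = map(int, np.argwhere(vals < 0)[0])
            raise ValueError(
                f"negative abundance {vals[r, c]} at sample {df.index[r]!r}, "
                f"taxon {df.columns[c]!r}"
            )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def require_analysis_ready(self) -> None:
        """Entry-point invariant: at least 2 samples and 2 taxa."""
        n, k = self.data.shape
        if n < 2 or k < 2:
            raise ValueError(f"need N >= 2 samples and K >= 2 taxa, got {n}x{k}")


@dataclass
class TaxonomyMap:
    """Per-taxon ordered lineage (finest rank first).

    ``lineage`` is indexed by taxon id with one column per rank, ordered
    fine-to-coarse (e.g. species, genus, family).  Lineages must be
    consistent: a taxon at any rank maps to exactly one ancestor at every
    coarser rank.
    """

    lineage: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineage
        if df.index.duplicated().any():
            raise ValueError("duplicated taxon ids in taxonomy")
        ranks = list(df.columns)
        for i, child in enumerate(ranks[:-1]):
            for parent in ranks[i + 1 :]:
                nuniq = df.groupby(child, sort=False)[parent].nunique()
                bad = nuniq[nuniq > 1]
                if len(bad):
                    raise ValueError(
                        f"inconsistent lineage: {child} value(s) "
                        f"{bad.index.tolist()} map to multiple {parent} values"
                    )

    @property
    def ranks(self) -> list[str]:
        return list(self.lineage.columns)

    def ancestor(self, taxon_ids: Iterable, rank: str) -> pd.Series:
        missing = [t for t in taxon_ids if t not in self.lineage.index]
        if missing:
            raise KeyError(f"taxa without lineage entry: {missing}")
        return self.lineage.loc[list(taxon_ids), rank]


@dataclass
class FeatureTable:
    """Samples x host features with declared per-column types.

    ``data`` holds numeric-coded values with NaN for missing;
    ``feature_types`` maps every column to one of ``continuous``, ``binary``
    or ``categorical``.  Binary columns must take exactly two non-missing
    values.
    """

    data: pd.DataFrame
    feature_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicated sample ids in feature table")
        if df.columns.duplicated().any():
            raise ValueError("duplicated feature ids")
        unknown = set(df.columns) - set(self.feature_types)
        if unknown:
            raise ValueError(f"features without a declared type: {sorted(unknown)}")
        for feat, ftype in self.feature_types.items():
            if ftype not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {ftype!r} for {feat!r}")
            if feat not in df.columns:
                raise ValueError(f"typed feature {feat!r} absent from table")
            if ftype == "binary":
                vals = df[feat].dropna().unique()
                if len(vals) != 2:
                    raise ValueError(
                        f"binary feature {feat!r} takes {len(vals)} distinct "
                        f"non-missing values, expected exactly 2"
                    )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            self.data[list(features)].copy(),
            {f: self.feature_types[f] for f in features},
        )


# ---------------------------------------------------------------------------
# TSV input / output


def read_abundance_table(path: str | Path, rank: str = "taxon") -> AbundanceTable:
    """Read a samples-as-rows, taxa-as-columns abundance TSV.

    The first column holds sample ids, the header row taxon ids.  Negative
    or missing values are rejected with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed abundance TSV {path}: {exc}") from exc
    return AbundanceTable(df, rank=rank)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    # repr of a Python float is the shortest exact representation, so
    # values survive the text round-trip bit-for-bit
    table.data.to_csv(
        path, sep="\t", index_label="sample_id",
        float_format=lambda v: repr(float(v)),
    )


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a one-row-per-taxon lineage TSV whose columns are rank names."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    taxonomy.lineage.to_csv(path, sep="\t", index_label="taxon_id")


def read_feature_table(path: str | Path, types_path: str | Path) -> FeatureTable:
    """Read a feature TSV plus its sidecar type file.

    The sidecar is a two-column TSV ``feature_id<TAB>type`` without header;
    "NA" marks missing values in the main table.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
    types = pd.read_csv(
        types_path, sep="\t", header=None, names=["feature_id", "type"], dtype=str
    )
    type_map = dict(zip(types["feature_id"], types["type"]))
    return FeatureTable(df, type_map)


def write_feature_table(
    features: FeatureTable, path: str | Path, types_path: str | Path
) -> None:
    features.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
    with open(types_path, "w") as fh:
        for feat in features.feature_ids:
            fh.write(f"{feat}\t{features.feature_types[feat]}\n")


# ---------------------------------------------------------------------------
# Aggregation and filtering


def aggregate_to_rank(
    table: AbundanceTable, taxonomy: TaxonomyMap, rank: str
) -> AbundanceTable:
    """Aggregate taxa to a coarser rank by summing abundances per sample.

    Each output column is one distinct ancestor at ``rank``; its value is
    the sum of the normalized abundances of all descendants present in the
    input, so per-sample totals are conserved exactly.
    """
    if rank == table.rank:
        return AbundanceTable(table.data.copy(), rank=rank)
    if rank not in taxonomy.ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy ranks {taxonomy.ranks}")
    try:
        ancestors = taxonomy.ancestor(table.taxon_ids, rank)
    except KeyError as exc:
        raise KeyError(f"cannot aggregate to {rank!r}: {exc}") from exc
    grouped = table.data.T.groupby(ancestors.to_numpy(), sort=False).sum().T
    return AbundanceTable(grouped, rank=rank)


def filter_taxa_by_prevalence(
    table: AbundanceTable, min_prevalence: float
) -> AbundanceTable:
    """Keep taxa detected (nonzero) in at least ``min_prevalence`` of samples.

    The boundary is inclusive: a taxon whose prevalence equals the threshold
    is kept.  Column order is preserved.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    prev = (table.values > 0).mean(axis=0)
    keep = prev >= min_prevalence
    if not keep.any():
        raise ValueError(
            f"no taxa reach prevalence {min_prevalence}; max observed {prev.max():.3f}"
        )
    return AbundanceTable(table.data.loc[:, keep], rank=table.rank)


def qc_features(
    features: FeatureTable,
    max_missing_frac: float = 0.5,
    min_binary_freq: float = 0.05,
    outlier_sd: float = 3.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Apply feature-level quality control and return (table, report).

    Rules, applied per feature:

    * any type: drop when the missing fraction exceeds ``max_missing_frac``;
    * binary: drop when the minor-class frequency (among non-missing values)
      is below ``min_binary_freq``;
    * categorical: categories whose numeric code lies more than
      ``outlier_sd`` standard deviations from the coded mean are merged into
      the nearest remaining category by coded value (ties broken toward the
      lower-frequency category).

    The report lists every input feature exactly once with action
    ``kept`` / ``dropped`` / ``merged`` and the reason.
    """
    if not 0 < max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in (0, 1)")
    report_rows: list[dict] = []
    kept_cols: list[str] = []
    out = features.data.copy()
    n = len(out)
    for feat in features.feature_ids:
        col = out[feat]
        ftype = features.feature_types[feat]
        miss = col.isna().mean()
        if miss > max_missing_frac:
            report_rows.append(
                {"feature": feat, "action": "dropped",
                 "reason": f"missing fraction {miss:.3f} > {max_missing_frac}"}
            )
            continue
        if ftype == "binary":
            freqs = col.dropna().value_counts(normalize=True)
            if freqs.min() < min_binary_freq:
                report_rows.append(
                    {"feature": feat, "action": "dropped",
                     "reason": f"minor-class frequency {freqs.min():.3f} < {min_binary_freq}"}
                )
                continue
        if ftype == "categorical":
            merged = _merge_outlier_categories(col, outlier_sd)
            if merged is not None:
                out[feat] = merged["values"]
                report_rows.append(
                    {"feature": feat, "action": "merged",
                     "reason": merged["reason"]}
                )
                kept_cols.append(feat)
                continue
        report_rows.append({"feature": feat, "action": "kept", "reason": ""})
        kept_cols.append(feat)
    if not kept_cols:
        warnings.warn("qc_features removed every feature", stacklevel=2)
    report = pd.DataFrame(report_rows, columns=["feature", "action", "reason"])
    qc_table = FeatureTable(
        out[kept_cols], {f: features.feature_types[f] for f in kept_cols}
    )
    return qc_table, report


def _merge_outlier_categories(col: pd.Series, outlier_sd: float) -> dict | None:
    """Merge numerically-outlying categories of one categorical column.

    Returns None when nothing is merged; otherwise a dict with the new
    values and a human-readable reason.
    """
    obs = col.dropna()
    mean = obs.mean()
    sd = obs.std(ddof=0)
    if sd == 0:
        return None
    counts = obs.value_counts()
    cats = counts.index.to_numpy(dtype=float)
    is_outlier = np.abs(cats - mean) > outlier_sd * sd
    if not is_outlier.any():
        return None
    remaining = cats[~is_outlier]
    if len(remaining) == 0:
        return None
    new = col.copy()
    moves = []
    for cat in cats[is_outlier]:
        dist = np.abs(remaining - cat)
        nearest = remaining[dist == dist.min()]
        # tie between equidistant categories -> the lower-occurring one
        target = min(nearest, key=lambda c: (counts.loc[c], c))
        new[col == cat] = target
        moves.append(f"{cat:g}->{target:g}")
    return {
        "values": new,
        "reason": f"outlier categories beyond {outlier_sd} sd merged: "
        + ", ".join(moves),
    }


def intersect_samples(
    abundance: AbundanceTable, features: FeatureTable
) -> tuple[AbundanceTable, FeatureTable]:
    """Align the two tables on their shared sample ids (order of abundance)."""
    shared = [s for s in abundance.sample_ids if s in set(features.sample_ids)]
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared samples between tables")
    return (
        AbundanceTable(abundance.data.loc[shared], rank=abundance.rank),
        FeatureTable(features.data.loc[shared], dict(features.feature_types)),
    )
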