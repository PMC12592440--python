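"""Co-abundance-variation networks from top contributing taxa pairs.

Nodes are taxa; an edge links a pair whose contribution to a predictor's
covariance signal ranks among the top k (or top fraction).  Edges carry the
per-predictor direction of effect; when predictors disagree on a shared
edge its status is "mixed".  Family-level summaries report how the top
pairs distribute across taxonomy: per-family incidence, the intra- versus
cross-family split, and a greedy minimal set of families covering at least
half of the top pairs.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatables import TaxonomyMap

__all__ = [
    "top_pairs",
    "build_network",
    "overlap_counts",
    "sign_proportions",
    "family_breakdown",
    "overlap_significance",
    "export_graphml",
    "read_graphml",
]


def top_pairs(
    pairs: pd.DataFrame,
    k: int | None = None,
    top_fraction: float | None = None,
) -> pd.DataFrame:
    """Select the top contributing pairs by descending phi.

    Exactly one of ``k`` (e.g. the top 1000 pairs) or ``top_fraction``
    (e.g. 0.05 for the top 5%) must be given.  Ties at the cut are broken
    deterministically by lexicographic (taxon_i, taxon_j) order.
    """
    if (k is None) == (top_fraction is None):
        raise ValueError("give exactly one of k or top_fraction")
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        k = max(1, int(round(top_fraction * len(pairs))))
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds number of pairs {len(pairs)}")
    ordered = pairs.sort_values(
        ["phi", "taxon_i", "taxon_j"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(k).reset_index(drop=True)


def build_network(edge_lists: dict[str, pd.DataFrame]) -> nx.Graph:
    """Union graph of per-predictor signed edge lists.

    Each edge stores its predictor membership, the per-predictor sign and a
    status: the common sign when all members agree, or ``"mixed"`` when
    shared predictors disagree on the direction of effect.  Node degree is
    the number of incident top pairs.
    """
    if not edge_lists:
        raise ValueError("need at least one predictor edge list")
    G = nx.Graph()
    for predictor, edges in edge_lists.items():
        for row in edges.itertuples(index=False):
            u, v, sign = row.taxon_i, row.taxon_j, int(row.sign)
            if G.has_edge(u, v):
                G[u][v]["signs"][predictor] = sign
            else:
                G.add_edge(u, v, signs={predictor: sign})
    for u, v, data in G.edges(data=True):
        signs = set(data["signs"].values())
        data["predictors"] = sorted(data["signs"])
        data["status"] = "mixed" if len(signs) > 1 else str(signs.pop())
    for node in G.nodes:
        members = set()
        for _, _, data in G.edges(node, data=True):
            members.update(data["predictors"])
        G.nodes[node]["predictors"] = sorted(members)
        G.nodes[node]["degree"] = G.degree(node)
    return G


def overlap_counts(edge_sets: dict[str, set]) -> dict[frozenset, int]:
    """Exact Venn-cell counts over per-predictor edge (or taxon) sets.

    Returns one count per non-empty predictor combination; cells partition
    the union, so their counts sum to its size.
    """
    if len(edge_sets) < 2:
        raise ValueError("need at least two sets")
    names = list(edge_sets)
    cells: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(edge_sets[c] for c in combo))
            outside = set.union(
                *(edge_sets[n] for n in names if n not in combo), set()
            )
            cells[frozenset(combo)] = len(inside - outside)
    return cells


def sign_proportions(edges: pd.DataFrame) -> dict[str, float]:
    """Fraction of top pairs with increasing / decreasing co-abundance."""
    n = len(edges)
    if n == 0:
        raise ValueError("empty edge list")
    pos = float((edges["sign"] > 0).mean())
    return {"increase": pos, "decrease": 1.0 - pos}


def family_breakdown(
    top_edges: pd.DataFrame,
    taxonomy: TaxonomyMap,
    family_rank: str = "family",
    cover_fraction: float = 0.5,
) -> dict:
    """Family-level summary of the top contributing pairs.

    Returns a dict with:

    * ``per_family`` — count of top edges incident to each family;
    * ``intra_fraction`` — share of edges with both endpoints in one family;
    * ``cover`` — greedy minimal list of families whose member taxa touch at
      least ``cover_fraction`` of the top edges.
    """
    genera = sorted(set(top_edges["taxon_i"]) | set(top_edges["taxon_j"]))
    fam = taxonomy.ancestor(genera, family_rank)
    fam_of = fam.to_dict()
    edges = list(zip(top_edges["taxon_i"], top_edges["taxon_j"]))
    per_family: dict[str, int] = {}
    intra = 0
    for u, v in edges:
        fu, fv = fam_of[u], fam_of[v]
        per_family[fu] = per_family.get(fu, 0) + 1
        if fu == fv:
            intra += 1
        else:
            per_family[fv] = per_family.get(fv, 0) + 1
    intra_fraction = intra / len(edges) if edges else 0.0
    cover = _greedy_family_cover(edges, fam_of, cover_fraction)
    per_family_df = (
        pd.Series(per_family, name="n_edges")
        .sort_values(ascending=False)
        .rename_axis("family")
        .reset_index()
    )
    return {
        "per_family": per_family_df,
        "intra_fraction": intra_fraction,
        "cross_fraction": 1.0 - intra_fraction,
        "cover": cover,
    }


def _greedy_family_cover(
    edges: list[tuple], fam_of: dict, cover_fraction: float
) -> list[str]:
    """Largest-marginal-gain set cover of edges by families.

    An edge is covered once either endpoint's family is selected; selection
    stops when at least ``cover_fraction`` of edges are covered.  Ties break
    alphabetically for determinism.
    """
    target = int(np.ceil(cover_fraction * len(edges)))
    uncovered = set(range(len(edges)))
    edges_of_family: dict[str, set[int]] = {}
    for idx, (u, v) in enumerate(edges):
        edges_of_family.setdefault(fam_of[u], set()).add(idx)
        edges_of_family.setdefault(fam_of[v], set()).add(idx)
    chosen: list[str] = []
    covered = 0
    while covered < target and len(chosen) < len(edges_of_family):
        best = max(
            (f for f in edges_of_family if f not in chosen),
            key=lambda f: (len(edges_of_family[f] & uncovered), f),
        )
        gain = edges_of_family[best] & uncovered
        if not gain:
            break
        chosen.append(best)
        uncovered -= gain
        covered = len(edges) - len(uncovered)
    return chosen


def overlap_significance(set_a: set, set_b: set, universe_size: int) -> float:
    """One-sided hypergeometric p-value of the observed set overlap.

    Probability of drawing at least the observed intersection when ``|B|``
    items are sampled without replacement from a universe containing
    ``|A|`` marked items.
    """
    na, nb = len(set_a), len(set_b)
    if na > universe_size or nb > universe_size:
        raise ValueError("set larger than universe")
    observed = len(set_a & set_b)
    return float(stats.hypergeom.sf(observed - 1, universe_size, na, nb))


def export_graphml(G: nx.Graph, path: str | Path) -> None:
    """GraphML export with list/dict attributes flattened to strings."""
    H = nx.Graph()
    for node, data in G.nodes(data=True):
        H.add_node(
            node,
            degree=int(data.get("degree", G.degree(node))),
            predictors=",".join(data.get("predictors", [])),
        )
    for u, v, data in G.edges(data=True):
        attrs = {
            "status": str(data.get("status", "")),
            "predictors": ",".join(data.get("predictors", [])),
        }
        for pred, sign in data.get("signs", {}).items():
            attrs[f"sign_{pred}"] = int(sign)
        H.add_edge(u, v, **attrs)
    nx.write_graphml(H, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    """Inverse of :func:`export_graphml` (restores membership lists and signs)."""
    H = nx.read_graphml(str(path))
    G = nx.Graph()
    for node, data in H.nodes(data=True):
        preds = [p for p in str(data.get("predictors", "")).split(",") if p]
        G.add_node(node, degree=int(data["degree"]), predictors=preds)
    for u, v, data in H.edges(data=True):
        signs = {
            key[len("sign_"):]: int(val)
            for key, val in data.items()
            if key.startswith("sign_")
        }
        preds = [p for p in str(data.get("predictors", "")).split(",") if p]
        G.add_edge(u, v, signs=signs, predictors=preds, status=str(data["status"]))
    return G
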