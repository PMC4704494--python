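"""Compound profile comparison: correlation, clustering, the interaction
network, and the resolution index (delta-AUC).

A compound's profile is its vector of pooled interaction coefficients over
(cell line, feature) cells; profile dissimilarity is 1 - Pearson
correlation, clustered with complete linkage. The resolution index
quantifies how well profile correlations separate compound pairs that
share target selectivity (or chemical structure) from pairs that do not:
it is the difference between the two classes' areas under the empirical
cumulative distribution function of pairwise correlations over [-1, 1] -
equivalently, how far the shared-class ECDF is shifted toward high
correlations.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .interactions import InteractionResult

__all__ = [
    "build_profiles",
    "profile_correlations",
    "cluster_profiles",
    "extract_clusters",
    "linkage_to_newick",
    "build_network",
    "classify_pairs",
    "ecdf_auc",
    "ResolutionIndex",
    "resolution_index",
    "PROFILE_SUBSETS",
]

PROFILE_SUBSETS = ("combined", "genotypes_only", "phenotypes_only")


def build_profiles(
    result: InteractionResult,
    subset: str = "combined",
    reference_line: str | None = None,
    cell_number: str = "cell_number",
) -> pd.DataFrame:
    """Flatten pooled interaction coefficients into compound profiles.

    ``combined`` uses all features across all cell lines; ``genotypes_only``
    uses the cell-number feature across all lines (pharmacogenetic view);
    ``phenotypes_only`` uses all features of the reference line (single-line
    multiparametric view, default the first line). Rows are compounds,
    columns ``line|feature`` cells.
    """
    if subset not in PROFILE_SUBSETS:
        raise ValueError(f"subset must be one of {PROFILE_SUBSETS}")
    pooled = result.pooled_pi()  # (D, L, F)
    lines, features = result.lines, result.features
    if subset == "genotypes_only":
        if cell_number not in features:
            raise ValueError(f"{cell_number!r} not among the features")
        pooled = pooled[:, :, [features.index(cell_number)]]
        features = [cell_number]
    elif subset == "phenotypes_only":
        ref = reference_line or lines[0]
        if ref not in lines:
            raise ValueError(f"reference line {ref!r} not in result")
        pooled = pooled[:, [lines.index(ref)], :]
        lines = [ref]
    cols = [f"{l}|{f}" for l in lines for f in features]
    return pd.DataFrame(
        pooled.reshape(pooled.shape[0], -1), index=result.compounds, columns=cols
    )


def profile_correlations(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of compound profiles.

    Symmetric with unit diagonal; missing cells are dropped pairwise.
    Constant (zero-variance) profiles have undefined correlations, returned
    as NaN with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    corr = profiles.T.corr(method="pearson")  # pandas drops NaN pairwise
    np.fill_diagonal(corr.values, 1.0)
    sds = profiles.std(axis=1, ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"constant profiles with undefined correlations: {constant}")
        corr.loc[constant, :] = np.nan
        corr.loc[:, constant] = np.nan
    return corr


def cluster_profiles(distance: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration of a 1-cor distance matrix.

    Returns the scipy linkage matrix; merge heights are nondecreasing.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(D, checks=False), method="complete")


def extract_clusters(
    Z: np.ndarray,
    labels: list[str],
    height_cut: float = 0.6,
    min_size: int = 3,
    max_size: int = 9,
) -> list[list[str]]:
    """Flat clusters below the height cut, filtered to the size window.

    Defaults mirror the map-building convention: cut the tree at 0.6 and
    keep clusters with more than 2 and fewer than 10 members (3..9).
    """
    assignment = hierarchy.fcluster(Z, t=height_cut, criterion="distance")
    clusters = []
    for k in np.unique(assignment):
        members = [labels[i] for i in np.flatnonzero(assignment == k)]
        if min_size <= len(members) <= max_size:
            clusters.append(sorted(members))
    return sorted(clusters, key=lambda c: (-len(c), c))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage dendrogram as a Newick string.

    Labels containing characters that are special in Newick (including
    underscores, which unquoted readers turn into spaces) are quoted.
    """
    tree = hierarchy.to_tree(Z)

    def _quote(label: str) -> str:
        if any(ch in label for ch in " _();:,'[]"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def _walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_quote(labels[node.id])}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"


def build_network(
    calls: pd.DataFrame,
    category_map: dict[str, str],
    max_genotypes: int = 3,
    min_features: int = 2,
    exclude_controls: bool = True,
    control_ids: tuple[str, ...] = ("vehicle", "kill_reference", "pathway_reference"),
) -> nx.Graph:
    """Bipartite genotype-compound map of the significant interactions.

    Compounds interacting with more than ``max_genotypes`` genetic
    backgrounds, or affecting fewer than ``min_features`` distinct
    phenotypic features, are filtered out (the map highlights selective,
    multi-phenotype interactions). An edge links a compound to a genotype
    when at least one significant feature falls in at least one phenotypic
    category for that pair; genotypes left without edges are omitted.
    """
    sig = calls[calls["significant"]].copy()
    if exclude_controls:
        sig = sig[~sig["compound_id"].isin(control_ids)]
    sig["category"] = sig["feature"].map(category_map)
    if sig["category"].isna().any():
        missing = sorted(sig.loc[sig["category"].isna(), "feature"].unique())
        raise ValueError(f"features without a category: {missing}")

    keep = []
    for cid, sub in sig.groupby("compound_id"):
        if sub["cell_line"].nunique() <= max_genotypes and sub["feature"].nunique() >= min_features:
            keep.append(cid)
    sig = sig[sig["compound_id"].isin(keep)]

    G = nx.Graph()
    for (cid, line), sub in sig.groupby(["compound_id", "cell_line"]):
        if not G.has_node(cid):
            G.add_node(cid, kind="compound")
        if not G.has_node(line):
            G.add_node(line, kind="genotype")
        G.add_edge(
            cid,
            line,
            categories=",".join(sorted(sub["category"].unique())),
            min_p_adj=float(sub["p_adj"].min()),
            n_features=int(sub["feature"].nunique()),
        )
    return G


def classify_pairs(
    targets: pd.DataFrame | None = None,
    distances: pd.DataFrame | None = None,
    structure_cutoff: float = 0.6,
    compounds: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify unordered compound pairs by shared target or structure.

    Exactly one scheme per call: with ``targets`` (columns ``compound_id``,
    ``target``; multiple targets separated by ';'), a pair is
    ``shared_selectivity`` iff the annotated target sets intersect. With
    ``distances`` (square matrix), a pair is ``similar_structure`` iff its
    distance is strictly below ``structure_cutoff``. Compounds missing from
    the annotation are excluded, with the exclusion count reported.
    """
    if (targets is None) == (distances is None):
        raise ValueError("provide exactly one of targets or distances")
    report = {"n_excluded_compounds": 0}
    if targets is not None:
        tmap = {
            row.compound_id: set(str(row.target).split(";"))
            for row in targets.itertuples()
        }
        universe = compounds if compounds is not None else sorted(tmap)
        known = [c for c in universe if c in tmap]
        report["n_excluded_compounds"] = len(universe) - len(known)
        rows = [
            (a, b, "shared_selectivity" if tmap[a] & tmap[b] else "no_shared_selectivity")
            for a, b in itertools.combinations(known, 2)
        ]
        cols = ["compound_a", "compound_b", "pair_class"]
        return pd.DataFrame(rows, columns=cols), report
    universe = compounds if compounds is not None else list(distances.index)
    known = [c for c in universe if c in distances.index]
    report["n_excluded_compounds"] = len(universe) - len(known)
    rows = [
        (
            a,
            b,
            "similar_structure"
            if float(distances.loc[a, b]) < structure_cutoff
            else "different_structure",
        )
        for a, b in itertools.combinations(known, 2)
    ]
    return pd.DataFrame(rows, columns=["compound_a", "compound_b", "pair_class"]), report


def ecdf_auc(values: np.ndarray, lo: float = -1.0, hi: float = 1.0) -> float:
    """Exact integral of the right-continuous ECDF step function over [lo, hi]."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("cannot integrate the ECDF of an empty sample")
    if x[0] < lo - 1e-12 or x[-1] > hi + 1e-12:
        raise ValueError(f"values must lie within [{lo}, {hi}]")
    x = np.clip(x, lo, hi)
    n = x.size
    edges = np.concatenate([[lo], x, [hi]])
    heights = np.arange(n + 1) / n  # ECDF value on each interval
    return float(np.sum(np.diff(edges) * heights))


_SHARED_CLASSES = {"shared_selectivity", "similar_structure"}


@dataclass
class ResolutionIndex:
    delta_auc: float
    auc_shared: float
    auc_other: float
    n_shared: int
    n_other: int
    n_undefined: int


def resolution_index(
    correlations: pd.DataFrame, pairs: pd.DataFrame
) -> ResolutionIndex:
    """Resolution index: delta-AUC between shared and non-shared pairs.

    For each pair class the ECDF of the profile correlations is integrated
    exactly over [-1, 1]; the index is AUC(non-shared) - AUC(shared) and is
    positive when shared pairs are more correlated (their ECDF is shifted
    right, hence has smaller area). Pairs with undefined correlations
    (constant profiles) are excluded, with the count reported.
    """
    shared, other = [], []
    n_undef = 0
    for row in pairs.itertuples():
        r = float(correlations.loc[row.compound_a, row.compound_b])
        if not np.isfinite(r):
            n_undef += 1
            continue
        (shared if row.pair_class in _SHARED_CLASSES else other).append(r)
    if not shared or not other:
        raise ValueError("both pair classes must be non-empty")
    auc_s = ecdf_auc(np.array(shared))
    auc_o = ecdf_auc(np.array(other))
    return ResolutionIndex(
        delta_auc=auc_o - auc_s,
        auc_shared=auc_s,
        auc_other=auc_o,
        n_shared=len(shared),
        n_other=len(other),
        n_undefined=n_undef,
    )
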