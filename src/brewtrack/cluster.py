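"""Temporal-profile clustering and set enrichment.

Proteins are mean-normalized per row (log2 value minus the row mean over
time points), filtered to those changing at least 2-fold over their mean in
some time point, hierarchically clustered with average linkage, and cut by
*node depth*: counting the root as depth 0, the clusters at depth d are the
leaf sets of all nodes exactly d merges below the root (leaves encountered
earlier stay singletons), so a cut at depth d yields at most 2**d clusters.
Clusters exceeding a size threshold are re-cut at a deeper node depth
within their own subtree.

The distance metric defaults to 1 - Pearson correlation across time points
(the usual choice for profile-shape clustering); Euclidean distance is
available. Pairs involving a constant (zero-variance) row have undefined
correlation and are assigned distance 1 (treated as uncorrelated).

Enrichment is a one-sided hypergeometric upper-tail test per term over a
detected-protein universe, BH-adjusted across terms with non-zero overlap.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import InputError
from .matrix import AbundanceMatrix


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values
    return matrix


def row_mean_normalize_filter(matrix, fold_threshold: float = 2.0) -> pd.DataFrame:
    """Centre each row on its mean and drop rows that never change enough.

    Input is a log2-scale proteins x time-points frame. A row is kept when
    ``max |value - row mean| >= log2(fold_threshold)`` over its detected
    time points (default 2-fold -> 1.0 log2 units).
    """
    df = _as_frame(matrix)
    if df.empty:
        raise InputError("empty matrix")
    if fold_threshold < 1.0:
        raise InputError("fold_threshold must be >= 1")
    centred = df.sub(df.mean(axis=1, skipna=True), axis=0)
    keep = centred.abs().max(axis=1, skipna=True) >= np.log2(fold_threshold)
    return centred[keep]


@dataclass
class ClusterTree:
    """Binary merge tree over proteins.

    ``linkage`` is a scipy linkage matrix; ``ids`` the leaf protein ids in
    input order; ``n_imputed`` counts residual missing cells filled with the
    row mean (0 on centred data) before distance computation.
    """

    linkage: np.ndarray
    ids: list[str]
    method: str
    metric: str
    n_imputed: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def max_depth(self) -> int:
        root = hierarchy.to_tree(self.linkage)
        best = 0
        stack = [(root, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf():
                best = max(best, d)
            else:
                stack.append((node.left, d + 1))
                stack.append((node.right, d + 1))
        return best

    def to_newick(self) -> str:
        """Serialize the merge tree in Newick format (branch lengths = merge heights)."""
        root = hierarchy.to_tree(self.linkage)
        sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * self.n_leaves + 100))

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            return (f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
                    f":{length:.6g}")

        return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"


def _correlation_distances(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances; constant rows get distance 1 to everything."""
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centred / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - r
    if constant.any():
        warnings.warn(f"{constant.sum()} constant row(s): correlation undefined, "
                      "distance 1 assigned", stacklevel=3)
        d[constant, :] = 1.0
        d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return squareform(d, checks=False)


def cluster_rows(matrix, method: str = "average", metric: str = "correlation") -> ClusterTree:
    """Deterministic agglomerative clustering of row profiles.

    Residual missing cells are imputed with the row mean (and counted);
    ties in merge distances are broken by scipy's deterministic ordering,
    so the tree is reproducible for a fixed row order.
    """
    df = _as_frame(matrix)
    if len(df) < 2:
        raise InputError("at least 2 rows are required for clustering")
    x = df.to_numpy(float)
    n_missing = int(np.isnan(x).sum())
    if n_missing:
        row_means = np.nanmean(x, axis=1)
        idx = np.where(np.isnan(x))
        x[idx] = np.take(row_means, idx[0])
    if metric == "correlation":
        condensed = _correlation_distances(x)
    elif metric == "euclidean":
        condensed = pdist(x, metric="euclidean")
    else:
        raise InputError(f"unsupported metric {metric!r}")
    z = hierarchy.linkage(condensed, method=method)
    return ClusterTree(linkage=z, ids=list(df.index), method=method, metric=metric,
                       n_imputed=n_missing)


def cut_at_node_depth(tree: ClusterTree, depth: int = 3,
                      large_cluster_size: int = 500,
                      refine_depth: int = 5) -> pd.DataFrame:
    """Extract clusters at a node depth, refining oversized clusters deeper.

    Returns a DataFrame indexed by protein id with columns ``cluster`` (the
    depth-``depth`` cluster, labelled 1..k in dendrogram order) and
    ``label`` (the final assignment: the cluster label, or ``"c.s"`` for a
    subcluster produced by re-cutting a cluster larger than
    ``large_cluster_size`` at ``refine_depth``).
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    if refine_depth <= depth:
        raise InputError("refine_depth must exceed depth")
    root = hierarchy.to_tree(tree.linkage)
    if depth > tree.max_depth():
        warnings.warn(f"depth {depth} exceeds tree height; every leaf becomes a "
                      "singleton cluster", stacklevel=2)

    def collect(node, node_depth: int, target: int):
        """Pre-order list of (node, depth) clusters at the target depth."""
        out = []
        stack = [(node, node_depth)]
        while stack:
            nd, d = stack.pop()
            if d == target or nd.is_leaf():
                out.append((nd, d))
            else:
                # push right first so the left subtree is processed first
                stack.append((nd.right, d + 1))
                stack.append((nd.left, d + 1))
        return out

    rows = []
    for c_label, (node, node_depth) in enumerate(collect(root, 0, depth), start=1):
        leaves = node.pre_order(lambda leaf: leaf.id)
        if len(leaves) > large_cluster_size and not node.is_leaf():
            for s_label, (sub, _) in enumerate(collect(node, node_depth, refine_depth), start=1):
                for leaf in sub.pre_order(lambda leaf: leaf.id):
                    rows.append((tree.ids[leaf], c_label, f"{c_label}.{s_label}"))
        else:
            for leaf in leaves:
                rows.append((tree.ids[leaf], c_label, str(c_label)))
    out = pd.DataFrame(rows, columns=["protein_id", "cluster", "label"])
    return out.set_index("protein_id").loc[tree.ids]


def hypergeom_tail_p(overlap, population_size, term_size, sample_size):
    """Upper-tail P(X >= overlap) for the enrichment 2x2 table (vectorizable)."""
    return stats.hypergeom.sf(np.asarray(overlap) - 1, population_size,
                              term_size, sample_size)


def enrich(selected, population, terms, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``terms`` maps term id -> member proteins (a mapping, or a DataFrame
    with columns term_id / protein_id). Only terms overlapping the selected
    set are tested; p-values are BH-adjusted across the tested terms and
    ``passes`` requires adjusted p < ``alpha``.
    """
    from .diffexpr import bh_adjust

    selected = set(selected)
    population = set(population)
    if not selected <= population:
        raise InputError("selected set must be a subset of the population")
    if isinstance(terms, pd.DataFrame):
        terms = {t: set(g["protein_id"]) for t, g in terms.groupby("term_id")}

    m = len(population)
    n = len(selected)
    rows = []
    for term_id in sorted(terms):
        members = set(terms[term_id]) & population
        k = len(members & selected)
        if k < 1:
            continue
        p = float(hypergeom_tail_p(k, m, len(members), n))
        rows.append({"term_id": term_id, "overlap": k, "sample_size": n,
                     "term_size": len(members), "population_size": m, "p_raw": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term_id", "overlap", "sample_size",
                                         "term_size", "population_size", "p_raw"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
        result["passes"] = result["p_adj"] < alpha
        result = result.sort_values(["p_adj", "p_raw", "term_id"]).reset_index(drop=True)
    else:
        result["p_adj"] = pd.Series(dtype=float)
        result["passes"] = pd.Series(dtype=bool)
    return result
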