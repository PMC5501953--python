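"""Expression analysis: variable genes, PCA, hierarchical clustering.

The workflow mirrors standard single-cell practice on normalized
transcript counts: select the most variable genes by variance of
log2(x+1)-transformed values (500 for PCA, 100 for heatmaps), transform
by log2(x+1) and mean-center each gene, run exact PCA, and cluster cells
hierarchically with 1 - Pearson correlation as the distance and average
linkage. Clusters cut from the dendrogram are labeled by marker-gene
sets (e.g. Gcg/Ins1/Ins2/Sst/Ppy for islet alpha/beta/delta/PP cells).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

__all__ = [
    "transform",
    "variable_genes",
    "pca",
    "hcluster",
    "dendrogram_newick",
    "label_clusters",
    "cell_pair_correlation",
]


def transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) then per-gene mean-centering (genes x cells in/out)."""
    logged = np.log2(normalized + 1.0)
    return logged.sub(logged.mean(axis=1), axis=0)


def variable_genes(normalized: pd.DataFrame, n: int) -> list[str]:
    """Top-n genes by variance of log2(x+1)-transformed values.

    Ties are broken lexicographically by gene id so the selection is
    deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    logged = np.log2(normalized + 1.0)
    var = logged.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def pca(transformed: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Exact PCA of cells over genes.

    Input is the genes x cells transformed matrix; output is a cells x
    components score DataFrame plus the variance-explained fractions.
    The sign of each component is fixed so its largest-magnitude gene
    loading is positive, making scores deterministic.
    """
    X = transformed.to_numpy().T  # cells x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two cells")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U[:, :k] * S[:k]
    total = (S ** 2).sum()
    var_explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=transformed.columns, columns=cols), var_explained


def _correlation_distance(transformed: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop constant-profile cells, return (kept matrix, condensed 1-r)."""
    X = transformed.to_numpy().T
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(transformed.columns, keep) if not k]
        warnings.warn(f"removing constant-profile cells: {dropped}", stacklevel=3)
        X = X[keep]
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    from scipy.spatial.distance import squareform

    kept = transformed.loc[:, keep]
    return kept, squareform(d, checks=False)


def hcluster(transformed: pd.DataFrame, k: int) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage hierarchical clustering with 1 - Pearson distance.

    Returns per-cell cluster labels (1..k from a maxclust cut) and the
    scipy linkage matrix. Cells with a constant profile (undefined
    correlation) are removed with a warning.
    """
    kept, condensed = _correlation_distance(transformed)
    Z = sch.linkage(condensed, method="average")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=kept.columns, name="cluster"), Z


def dendrogram_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = sch.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def label_clusters(
    clusters: pd.Series,
    normalized: pd.DataFrame,
    marker_sets: Mapping[str, Sequence[str]],
) -> dict[int, str]:
    """Label each cluster by its highest-scoring marker set.

    The score of a marker set in a cluster is the mean normalized
    expression of its genes over the cluster's cells; ties yield
    "unresolved". Marker sets must be disjoint.
    """
    all_markers = [g for gs in marker_sets.values() for g in gs]
    if len(all_markers) != len(set(all_markers)):
        raise ValueError("marker sets must be disjoint")
    out: dict[int, str] = {}
    for cl in sorted(clusters.unique()):
        cells = clusters.index[clusters == cl]
        scores = {}
        for name, genes in marker_sets.items():
            present = [g for g in genes if g in normalized.index]
            scores[name] = float(normalized.loc[present, cells].to_numpy().mean()) \
                if present else float("-inf")
        best = max(scores.values())
        winners = [name for name, s in scores.items() if s == best]
        out[int(cl)] = winners[0] if len(winners) == 1 else "unresolved"
    return out


def cell_pair_correlation(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between cell profiles.

    ``values`` is genes x cells of per-gene transcript counts or per-gene
    read counts — running both reproduces the UMI advantage, where
    transcript-level profiles correlate more strongly between cells than
    read-level profiles inflated by PCR duplication.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two cells")
    r = np.corrcoef(values.to_numpy().T)
    return pd.DataFrame(r, index=values.columns, columns=values.columns)
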