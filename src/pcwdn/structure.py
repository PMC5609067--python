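"""Transcriptome structure: filtering, log transform, correlation, PCA, clustering.

The recipe mirrors the classic expression-clustering workflow: drop genes
that never reach 10 FPKM in any condition, log2-transform with a
pseudocount, center each gene on the log of its geometric mean across
conditions (optionally scaling rows to unit norm), then examine structure
through pairwise condition correlation with average-linkage hierarchical
clustering on 1 - Pearson r, principal-component variance fractions over
conditions, and average-linkage gene clustering cut to a requested number
of clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TransformParams",
    "PCAResult",
    "filter_low_expression",
    "transform",
    "condition_correlation",
    "pca_conditions",
    "cluster_genes",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class TransformParams:
    fpkm_floor: float = 10.0
    pseudocount: float = 1.0
    scale_rows: bool = True

    def __post_init__(self) -> None:
        if self.fpkm_floor < 0:
            raise ValueError("fpkm_floor must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class PCAResult:
    variance_fractions: tuple[float, ...]


def filter_low_expression(means: pd.DataFrame, params: TransformParams = TransformParams()) -> pd.DataFrame:
    """Keep genes reaching the FPKM floor in at least one condition (inclusive)."""
    keep = (means >= params.fpkm_floor).any(axis=1)
    return means.loc[keep]


def transform(means: pd.DataFrame, params: TransformParams = TransformParams()) -> pd.DataFrame:
    """log2(x + pseudocount), per-gene geometric-mean centering, optional unit-norm rows."""
    logged = np.log2(means.to_numpy(dtype=float) + params.pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    if params.scale_rows:
        norms = np.linalg.norm(centered, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            centered = np.where(norms > 0, centered / np.where(norms == 0, 1, norms), 0.0)
    return pd.DataFrame(centered, index=means.index, columns=means.columns)


def _pearson_distance_linkage(rows: np.ndarray) -> np.ndarray:
    """Average-linkage tree on 1 - Pearson correlation between rows."""
    r = np.corrcoef(rows)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def condition_correlation(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Pearson correlation between condition columns + linkage tree.

    Returns the symmetric correlation DataFrame (unit diagonal) and the
    scipy linkage matrix over conditions, built on 1 - r with average
    linkage.  A zero-variance condition makes the correlation undefined and
    raises, naming the condition.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two conditions")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    dead = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance condition(s): {', '.join(map(str, dead))}")
    corr = pd.DataFrame(
        np.corrcoef(vals.T), index=matrix.columns, columns=matrix.columns
    )
    return corr, _pearson_distance_linkage(vals.T)


def pca_conditions(matrix: pd.DataFrame) -> PCAResult:
    """Variance fractions of principal components over conditions.

    Conditions are observations, genes variables; columns of the
    observation matrix (condition x gene) are mean-centered and the
    fractions come from the singular values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two conditions")
    obs = matrix.to_numpy(dtype=float).T  # conditions x genes
    obs = obs - obs.mean(axis=0, keepdims=True)
    s = np.linalg.svd(obs, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has no variance across conditions")
    return PCAResult(variance_fractions=tuple(np.sort(var / total)[::-1]))


def cluster_genes(matrix: pd.DataFrame, n_clusters: int) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage/1 - Pearson gene clustering cut to ``n_clusters``.

    Gene rows are sorted lexicographically before linkage so the merge
    order, and hence the labelling, is deterministic.  Constant rows (whose
    correlation with anything is undefined) are excluded with a warning.
    Returns (gene -> cluster label Series, linkage matrix over the retained
    genes in sorted order).
    """
    matrix = matrix.sort_index()
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        dropped = matrix.index[sd == 0].tolist()
        warnings.warn(
            f"excluding {len(dropped)} constant gene row(s) with undefined correlation: "
            + ", ".join(map(str, dropped[:5]))
        )
        matrix = matrix.loc[sd > 0]
        vals = matrix.to_numpy(dtype=float)
    n = len(matrix)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    Z = _pearson_distance_linkage(vals)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster"), Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
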