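"""Fold-change similarity: Pearson correlation, clustering, heatmap export.

Cross-study similarity is assessed on average log2 fold changes (never on
absolute signals).  Hierarchical clustering follows the Eisen-style
convention: uncentered-correlation (cosine) distance with average linkage by
default; centered correlation and Euclidean distance are selectable.  For
display, fold changes are clamped to [−3, 3]; statistics always use the
unclamped values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "clamp_fc",
    "pearson_fc_correlation",
    "hierarchical_cluster",
    "ClusterResult",
    "plot_heatmap",
]

CLAMP_RANGE = (-3.0, 3.0)


def clamp_fc(fc, lo: float = CLAMP_RANGE[0], hi: float = CLAMP_RANGE[1]):
    """Clamp fold changes into [lo, hi] for display (idempotent, monotone)."""
    if lo > hi:
        raise ValueError("clamp_fc: lo must be <= hi")
    return fc.clip(lower=lo, upper=hi) if hasattr(fc, "clip") else np.clip(fc, lo, hi)


def pearson_fc_correlation(fc_x, fc_y) -> tuple[float, float]:
    """Sample Pearson r between two aligned fold-change vectors, with its
    two-sided p-value from the t transform on n − 2 degrees of freedom."""
    x = np.asarray(fc_x, float)
    y = np.asarray(fc_y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_fc_correlation: vectors must be aligned 1-D")
    if x.size < 3:
        raise ValueError("pearson_fc_correlation: need at least 3 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_fc_correlation: zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ClusterResult:
    """Agglomeration result: linkage matrix, leaf order, and Newick tree."""

    linkage: np.ndarray
    order: list[str]
    newick: str


def _distance(values: np.ndarray, index, metric: str) -> np.ndarray:
    if metric == "uncentered":
        norms = np.sqrt((values**2).sum(axis=1))
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(
                f"hierarchical_cluster: all-zero row(s) undefined under uncentered "
                f"correlation: {[index[i] for i in bad[:5]]}"
            )
        return pdist(values, metric="cosine")
    if metric == "correlation":
        bad = np.flatnonzero(values.std(axis=1) == 0)
        if bad.size:
            raise ValueError(
                f"hierarchical_cluster: constant row(s) undefined under correlation "
                f"distance: {[index[i] for i in bad[:5]]}"
            )
        return pdist(values, metric="correlation")
    if metric == "euclidean":
        return pdist(values, metric="euclidean")
    raise ValueError(f"unknown metric {metric!r}")


def hierarchical_cluster(
    fc: pd.DataFrame, metric: str = "uncentered", linkage: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of fold-change rows.

    ``metric`` is one of ``uncentered`` (1 − uncentered correlation, the
    Eisen-clustering convention, equal to cosine distance), ``correlation``
    or ``euclidean``; ``linkage`` is any scipy linkage method (default
    average).  Returns the merge tree, the dendrogram leaf order, and the
    tree serialized as Newick with gene ids as leaf names.
    """
    if fc.shape[0] < 2:
        raise ValueError("hierarchical_cluster: need at least 2 rows")
    values = fc.to_numpy(float)
    if np.isnan(values).any():
        raise ValueError("hierarchical_cluster: missing values in fold-change matrix")
    ids = [str(i) for i in fc.index]
    dist = _distance(values, ids, metric)
    z = hierarchy.linkage(dist, method=linkage)
    order = [ids[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(linkage=z, order=order, newick=_to_newick(z, ids))


def _to_newick(z: np.ndarray, ids: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, ids)
    return str(tree).strip()


def plot_heatmap(
    fc: pd.DataFrame,
    path,
    order: list[str] | None = None,
    clamp: tuple[float, float] = CLAMP_RANGE,
    cmap: str = "RdBu_r",
) -> None:
    """Write a clamped fold-change heatmap (rows optionally in cluster order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = fc.loc[order] if order is not None else fc
    clamped = clamp_fc(data, *clamp)
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.6 * fc.shape[1] + 2.0), max(3.0, 0.045 * fc.shape[0] + 1.5))
    )
    im = ax.imshow(
        clamped.to_numpy(float),
        aspect="auto",
        cmap=cmap,
        vmin=clamp[0],
        vmax=clamp[1],
        interpolation="nearest",
    )
    ax.set_xticks(range(clamped.shape[1]))
    ax.set_xticklabels([str(c) for c in clamped.columns], rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{clamped.shape[0]} genes")
    fig.colorbar(im, ax=ax, label="average log2FC (clamped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
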