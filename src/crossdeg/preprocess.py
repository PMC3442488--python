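"""Normalization, detection filtering, gene aggregation and homolog merging.

The preprocessing chain for each study is: quantile-normalize the log2
matrix, drop features that are not reliably detected (only where detection
p-values exist, i.e. the bead-array study), average probes into gene-centered
features, then restrict both studies to the shared homolog universe and
re-normalize the merged matrices so that differing log2 signal ranges cannot
bias downstream fold-change comparisons.  Cross-species inference downstream
uses relative (fold-change) quantities only; absolute signals of different
platforms are never compared directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionStudy, HomologMap, MergedStudy

__all__ = [
    "quantile_normalize",
    "detection_filter",
    "aggregate_by_gene",
    "merge_by_homologs",
    "renormalize_merged",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean empirical distribution.

    After the call each column's sorted values equal the across-column mean of
    order statistics.  Tied values within a column receive the mean of the
    normalized values at their tied ranks, which makes the result invariant to
    any within-column permutation of equal values.
    """
    if matrix.shape[0] == 0:
        raise ValueError("quantile_normalize: matrix has zero rows")
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile_normalize: matrix contains missing values")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average assigned values over groups of tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_filter(
    study: ExpressionStudy, alpha: float = 0.01, min_samples: int = 4
) -> ExpressionStudy:
    """Keep features detected (p < ``alpha``) in at least ``min_samples`` samples."""
    if study.detection_p is None:
        raise ValueError(
            f"{study.name}: no detection p-values available — skip detection_filter "
            "for this study"
        )
    detected = (study.detection_p < alpha).sum(axis=1) >= min_samples
    keep = study.matrix.index[detected.to_numpy()]
    return study.with_matrix(
        study.matrix.loc[keep], detection_p=study.detection_p.loc[keep]
    )


def aggregate_by_gene(study: ExpressionStudy, probe_map: pd.DataFrame) -> ExpressionStudy:
    """Agglomerate probe-level rows into one gene-centered row per gene.

    Each gene's row is the arithmetic mean of its probes' log2 values per
    sample; probes without a gene mapping are dropped.
    """
    pm = probe_map.astype(str).set_index("probe_id")["gene_id"]
    mapped = study.matrix.index.intersection(pm.index)
    if len(mapped) == 0:
        raise ValueError(f"{study.name}: no feature is covered by the probe map")
    genes = pm.loc[mapped]
    agg = study.matrix.loc[mapped].groupby(genes.to_numpy()).mean()
    agg.index.name = "gene_id"
    return study.with_matrix(agg)


def merge_by_homologs(
    study_a: ExpressionStudy, study_b: ExpressionStudy, homolog_map: HomologMap
) -> MergedStudy:
    """Restrict both gene-level studies to homolog pairs present in each.

    Rows of the merged matrices are indexed by the study-A gene id of each
    pair, in identical order; ``m`` (the shared-homolog universe size) is the
    number of surviving pairs.
    """
    pairs = homolog_map.pairs
    present = pairs["gene_a"].isin(study_a.matrix.index) & pairs["gene_b"].isin(
        study_b.matrix.index
    )
    pairs = pairs.loc[present].reset_index(drop=True)
    if len(pairs) == 0:
        raise ValueError("merge_by_homologs: no homolog pair present in both studies")
    matrix_a = study_a.matrix.loc[pairs["gene_a"]].copy()
    matrix_b = study_b.matrix.loc[pairs["gene_b"]].copy()
    key = pd.Index(pairs["gene_a"], name="homolog_key")
    matrix_a.index = key
    matrix_b.index = key
    return MergedStudy(matrix_a=matrix_a, matrix_b=matrix_b, pairs=pairs)


def renormalize_merged(merged: MergedStudy) -> MergedStudy:
    """Quantile-normalize each study's restricted matrix independently.

    Applied after merging so that the two studies' differing log2 signal
    ranges cannot bias fold-change comparisons.  The studies are normalized
    separately, never pooled: absolute signals are not comparable across
    platforms, so only within-study distributions are equalized.
    """
    return merged.with_matrices(
        quantile_normalize(merged.matrix_a), quantile_normalize(merged.matrix_b)
    )
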