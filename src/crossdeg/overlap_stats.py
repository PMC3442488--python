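"""Significance of DEG-list intersections and the common-DEG (DEGC) set.

Two complementary nulls are offered for the question "could lists this large
intersect this much by chance, given a shared universe of m genes?": the
exact hypergeometric upper tail for two lists, and a Monte-Carlo resampling
null (same-size uniform random subsets of the universe, default 4,000
iterations) that extends to three or more lists.  The common DEG set is

    DEGC = (DEG(cond1, any time) ∪ DEG(cond2, any time)) ∩ DEG(other study, any time)

and is partitioned by cross-species sign concordance of the per-study
average log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "hypergeometric_overlap",
    "mcs_overlap",
    "build_degc",
    "sign_concordance",
]


@dataclass
class OverlapResult:
    """Observed intersection size with exact and/or Monte-Carlo p-values.

    ``p_mcs`` is the literal strictly-greater empirical fraction
    #{null > observed}/iterations; ``p_mcs_pseudocount`` is the
    (#{null >= observed}+1)/(iterations+1) variant, which cannot return an
    exact zero and is the better-calibrated estimator.
    """

    observed: int
    m: int
    set_sizes: tuple[int, ...]
    p_hyper: float | None = None
    p_mcs: float | None = None
    p_mcs_pseudocount: float | None = None
    null: np.ndarray | None = field(default=None, repr=False)
    iterations: int | None = None
    seed: int | None = None

    def summary(self) -> dict:
        out = {
            "observed": self.observed,
            "m": self.m,
            "set_sizes": list(self.set_sizes),
        }
        for k in ("p_hyper", "p_mcs", "p_mcs_pseudocount", "iterations", "seed"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def _check_subsets(sets, universe):
    universe = frozenset(str(g) for g in universe)
    clean = []
    for i, s in enumerate(sets):
        s = frozenset(str(g) for g in s)
        if not s <= universe:
            extra = sorted(s - universe)[:5]
            raise ValueError(f"set {i} is not contained in the universe, e.g. {extra}")
        clean.append(s)
    return clean, universe


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Exact upper-tail p for the overlap of two gene sets in a finite universe.

    p = P[X >= observed] for X ~ Hypergeometric(m, |B|, |A|): the chance that
    |A| genes drawn uniformly from the universe hit at least the observed
    number of members of B.
    """
    (sa, sb), uni = _check_subsets([set_a, set_b], universe)
    m = len(uni)
    observed = len(sa & sb)
    p = float(stats.hypergeom.sf(observed - 1, m, len(sb), len(sa)))
    return OverlapResult(
        observed=observed, m=m, set_sizes=(len(sa), len(sb)), p_hyper=min(p, 1.0)
    )


def mcs_overlap(
    sets,
    universe,
    iterations: int = 4000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    chunk: int = 512,
) -> OverlapResult:
    """Monte-Carlo null for the K-way intersection of 2..K gene sets.

    Each iteration draws, for every input set, a uniform random subset of the
    universe of the same size (without replacement) and records the size of
    the K-way intersection.  Both empirical p-value conventions are reported;
    the run is fully determined by ``seed``.
    """
    if iterations < 1:
        raise ValueError("mcs_overlap: iterations must be >= 1")
    if len(sets) < 2:
        raise ValueError("mcs_overlap: need at least two sets")
    clean, uni = _check_subsets(sets, universe)
    m = len(uni)
    observed = len(frozenset.intersection(*clean))
    sizes = [len(s) for s in clean]
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(iterations, dtype=np.int64)
    done = 0
    while done < iterations:
        nit = min(chunk, iterations - done)
        inter = np.ones((nit, m), dtype=bool)
        for size in sizes:
            if size == 0:
                inter[:] = False
                continue
            r = rng.random((nit, m))
            kth = np.partition(r, size - 1, axis=1)[:, size - 1 : size]
            inter &= r <= kth  # exactly `size` entries per row (continuous, no ties)
        null[done : done + nit] = inter.sum(axis=1)
        done += nit
    p_gt = float(np.mean(null > observed))
    p_ge = float((np.sum(null >= observed) + 1) / (iterations + 1))
    return OverlapResult(
        observed=observed,
        m=m,
        set_sizes=tuple(sizes),
        p_mcs=p_gt,
        p_mcs_pseudocount=p_ge,
        null=null,
        iterations=iterations,
        seed=seed,
    )


def build_degc(deg_b_cond1, deg_b_cond2, deg_a) -> set[str]:
    """Common DEG set: (∪ cond1 ∪ cond2) ∩ (∪ study-A time points).

    Each argument is an iterable of gene-ID sets (one per time point); within
    each family the union over time points is taken first, so a gene counts as
    differentially expressed if it passes at any time.
    """

    def _union(family):
        out: set[str] = set()
        for s in family:
            out |= {str(g) for g in s}
        return out

    return (_union(deg_b_cond1) | _union(deg_b_cond2)) & _union(deg_a)


def sign_concordance(
    degc, fc_a: pd.DataFrame, fc_b: pd.DataFrame
) -> pd.DataFrame:
    """Partition DEGC by agreement of average fold-change direction.

    ``fc_a``/``fc_b`` are gene × contrast frames of log2 fold changes (NaN
    where a contrast does not cover a gene).  Per gene the log2FC is averaged
    over each study's contrasts where defined; a gene is discordant when the
    two averages have opposite signs, concordant when they agree, and
    indeterminate when either average is exactly zero.
    """
    degc = sorted({str(g) for g in degc})
    missing = [
        g
        for g in degc
        if g not in fc_a.index
        or g not in fc_b.index
        or not np.isfinite(fc_a.loc[g].to_numpy(float)).any()
        or not np.isfinite(fc_b.loc[g].to_numpy(float)).any()
    ]
    if missing:
        raise ValueError(f"sign_concordance: no fold change for genes {missing[:10]}")
    avg_a = fc_a.loc[degc].mean(axis=1, skipna=True)
    avg_b = fc_b.loc[degc].mean(axis=1, skipna=True)
    sign_a = np.sign(avg_a.to_numpy())
    sign_b = np.sign(avg_b.to_numpy())
    concordance = np.where(
        (sign_a == 0) | (sign_b == 0),
        "indeterminate",
        np.where(sign_a == sign_b, "concordant", "discordant"),
    )
    return pd.DataFrame(
        {
            "avg_log2fc_a": avg_a,
            "avg_log2fc_b": avg_b,
            "concordance": concordance,
        },
        index=pd.Index(degc, name="gene_id"),
    )
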