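"""Moderated-t differential expression with the MAQC dual criterion.

For a two-group contrast the per-gene statistic is an empirical-Bayes
moderated t: the gene-wise residual variance s_g² (pooled over the two
groups, d_g degrees of freedom) is shrunk toward a prior (d0, s0²) estimated
from all genes by moment matching on log variances, giving the posterior
variance

    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g)

and t_g = log2FC_g / (s̃_g·sqrt(1/n1 + 1/n2)) referred to a t distribution on
d0 + d_g degrees of freedom (a normal reference when d0 = ∞).  A gene is
called differentially expressed (DEG) when it passes both MAQC criteria:
|log2FC| of at least one (i.e. an average twofold change, boundary included)
and a Benjamini–Hochberg adjusted p-value below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Contrast",
    "ModeratedTModel",
    "compute_log2fc",
    "pooled_variance",
    "fit_variance_prior",
    "trigamma_inverse",
    "moderated_t",
    "bh_adjust",
    "call_deg",
    "de_table",
]


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison, resolved to explicit sample lists."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self):
        if len(self.numerator) == 0 or len(self.denominator) == 0:
            raise ValueError(f"contrast {self.name!r}: empty sample group")
        if set(self.numerator) & set(self.denominator):
            raise ValueError(f"contrast {self.name!r}: groups overlap")

    @classmethod
    def from_groups(cls, name, samples, numerator, denominator):
        """Build a contrast from (group, time) selectors against a sample sheet.

        ``numerator``/``denominator`` are ``(group_label, time)`` pairs; a
        ``time`` of None selects every sample of that group.
        """

        def _select(spec):
            group, time = spec
            mask = samples["group"] == group
            if time is not None:
                mask &= samples["time"] == time
            sel = tuple(samples.index[mask])
            if not sel:
                raise ValueError(
                    f"contrast {name!r}: no samples for group={group!r}, time={time!r}"
                )
            return sel

        return cls(name, _select(numerator), _select(denominator))

    @property
    def n1(self) -> int:
        return len(self.numerator)

    @property
    def n2(self) -> int:
        return len(self.denominator)

    @property
    def residual_df(self) -> int:
        return self.n1 + self.n2 - 2

    def flipped(self) -> "Contrast":
        return Contrast(f"{self.name}(flipped)", self.denominator, self.numerator)


@dataclass(frozen=True)
class ModeratedTModel:
    """Variance prior: d0 prior degrees of freedom (∞ allowed), s0² prior scale."""

    d0: float
    s0sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0sq > 0):
            raise ValueError("s0sq must be > 0")

    def posterior_variance(self, s2: np.ndarray, df: np.ndarray) -> np.ndarray:
        s2 = np.asarray(s2, float)
        df = np.asarray(df, float)
        if np.isinf(self.d0):
            return np.full_like(s2, self.s0sq)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s0sq + df * s2) / (self.d0 + df)


def _group_arrays(matrix: pd.DataFrame, contrast: Contrast):
    missing = (set(contrast.numerator) | set(contrast.denominator)) - set(matrix.columns)
    if missing:
        raise ValueError(f"contrast {contrast.name!r}: samples absent from matrix: {sorted(missing)}")
    x = matrix.loc[:, list(contrast.numerator)].to_numpy(float)
    y = matrix.loc[:, list(contrast.denominator)].to_numpy(float)
    return x, y


def compute_log2fc(matrix: pd.DataFrame, contrast: Contrast) -> pd.Series:
    """Per-gene mean log2 difference, numerator minus denominator."""
    x, y = _group_arrays(matrix, contrast)
    return pd.Series(x.mean(axis=1) - y.mean(axis=1), index=matrix.index, name="log2fc")


def pooled_variance(matrix: pd.DataFrame, contrast: Contrast) -> tuple[pd.Series, int]:
    """Pooled two-group residual variance and its degrees of freedom."""
    x, y = _group_arrays(matrix, contrast)
    df = contrast.residual_df
    if df <= 0:
        raise ValueError(
            f"contrast {contrast.name!r}: needs >= 2 total replicates beyond groups"
        )
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return pd.Series(ss / df, index=matrix.index, name="s2"), df


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ψ′(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def fit_variance_prior(s2, df, min_genes: int = 50) -> ModeratedTModel:
    """Estimate the variance prior (d0, s0²) by moment matching on log s².

    With e_g = log s_g² − ψ(d_g/2) + log(d_g/2), the between-gene dispersion of
    e in excess of the sampling component mean ψ′(d_g/2) estimates ψ′(d0/2);
    inverting the trigamma gives d0, and the mean ē then yields
    s0² = exp(ē + ψ(d0/2) − log(d0/2)).  When the excess dispersion is ≤ 0 the
    variances are more concentrated than any finite prior allows: d0 = ∞ and
    s0² is the mean sample variance.
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape).copy()
    ok = np.isfinite(s2) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < min_genes:
        raise ValueError(f"fit_variance_prior: needs >= {min_genes} genes with df >= 1")
    if np.all(s2 == 0):
        raise ValueError("fit_variance_prior: all residual variances are zero")
    # guard exact zeros (constant genes) the way variance-shrinkage fits do
    s2 = np.maximum(s2, 1e-5 * np.median(s2[s2 > 0]))
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(s2.mean())
    return ModeratedTModel(d0=float(d0), s0sq=s0sq)


def moderated_t(
    matrix: pd.DataFrame, contrast: Contrast, model: ModeratedTModel
) -> pd.DataFrame:
    """Moderated t-statistics for one contrast under a fitted variance prior.

    Returns a frame indexed by gene with columns ``log2fc``, ``s2``, ``t``,
    ``df`` (total = d0 + d_g) and ``p_raw`` (two-sided).
    """
    if contrast.n1 < 2 or contrast.n2 < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: each group needs >= 2 samples for a t-test"
        )
    fc = compute_log2fc(matrix, contrast)
    s2, dg = pooled_variance(matrix, contrast)
    post = model.posterior_variance(s2.to_numpy(), dg)
    se = np.sqrt(post * (1.0 / contrast.n1 + 1.0 / contrast.n2))
    t = fc.to_numpy() / se
    if np.isinf(model.d0):
        df_total = np.inf
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        df_total = model.d0 + dg
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "s2": s2,
            "t": t,
            "df": df_total,
            "p_raw": p,
        },
        index=matrix.index,
    )


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_raw, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deg(
    result: pd.DataFrame,
    fc_fold: float = 2.0,
    alpha: float = 0.05,
    inclusive_fold: bool = True,
) -> set[str]:
    """Genes passing both MAQC criteria: fold change and adjusted p.

    ``fc_fold`` is on the linear scale (2 = twofold, i.e. |log2FC| >= 1); the
    fold-change boundary is included by default.
    """
    lfc = result["log2fc"].abs()
    thr = np.log2(fc_fold)
    fc_ok = lfc >= thr if inclusive_fold else lfc > thr
    sig = result["p_adj"] < alpha
    return set(result.index[(fc_ok & sig).to_numpy()])


def de_table(
    matrix: pd.DataFrame,
    contrast: Contrast,
    model: ModeratedTModel | None = None,
    fc_fold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-gene DE result for one contrast (fits the prior if not given)."""
    if model is None:
        s2, dg = pooled_variance(matrix, contrast)
        model = fit_variance_prior(s2, dg)
    res = moderated_t(matrix, contrast, model)
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    deg = call_deg(res, fc_fold=fc_fold, alpha=alpha)
    res["is_deg"] = res.index.isin(sorted(deg))
    res.insert(0, "contrast", contrast.name)
    res.attrs["model"] = model
    return res
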