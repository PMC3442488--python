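"""Core in-memory containers shared across the pipeline stages.

An :class:`ExpressionStudy` is one species' feature × sample matrix of log2
intensities together with its sample sheet (group label, time point, control
flag) and, optionally, per-feature detection p-values.  A :class:`HomologMap`
carries the platform probe → gene maps and the cross-species gene pairing that
defines the shared-homolog universe; a :class:`MergedStudy` is the pair of
gene × sample matrices restricted to that universe.

All feature, gene and sample identifiers are handled as strings so that
matrices round-trip losslessly through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy", "HomologMap", "MergedStudy"]

REQUIRED_SAMPLE_COLUMNS = ("group", "time", "is_control")


def _as_str_index(idx) -> pd.Index:
    return pd.Index([str(i) for i in idx])


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix plus sample annotations.

    Parameters
    ----------
    matrix
        Feature × sample matrix of log2 intensities.  Row index = feature
        (probe or gene) identifiers, columns = sample names.
    samples
        Sample sheet indexed by sample name with columns ``group`` (label),
        ``time`` (numeric time point; NaN for samples without one, e.g.
        controls) and ``is_control`` (bool).
    detection_p
        Optional feature × sample detection p-values aligned with ``matrix``.
    name
        Free-text study label used in messages and file names.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    name: str = "study"

    def __post_init__(self) -> None:
        self.matrix = self.matrix.copy()
        self.matrix.index = _as_str_index(self.matrix.index)
        self.matrix.columns = _as_str_index(self.matrix.columns)
        self.samples = self.samples.copy()
        self.samples.index = _as_str_index(self.samples.index)
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"{self.name}: sample sheet lacks column {col!r}")
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][:5].tolist()
            raise ValueError(f"{self.name}: duplicate feature ids, e.g. {dup}")
        missing = set(self.matrix.columns) - set(self.samples.index)
        if missing:
            raise ValueError(
                f"{self.name}: samples missing from sample sheet: {sorted(missing)[:5]}"
            )
        # keep sample sheet restricted & ordered to the matrix columns
        self.samples = self.samples.loc[list(self.matrix.columns)]
        if self.samples["group"].isna().any():
            raise ValueError(f"{self.name}: every sample needs a group label")
        if not self.samples["is_control"].astype(bool).any():
            raise ValueError(f"{self.name}: at least one control sample required")
        if self.detection_p is not None:
            self.detection_p = self.detection_p.copy()
            self.detection_p.index = _as_str_index(self.detection_p.index)
            self.detection_p.columns = _as_str_index(self.detection_p.columns)
            if not self.detection_p.index.equals(self.matrix.index) or not (
                self.detection_p.columns.equals(self.matrix.columns)
            ):
                raise ValueError(f"{self.name}: detection_p not aligned with matrix")
            vals = self.detection_p.to_numpy(float)
            if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{self.name}: detection p-values must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["is_control"].astype(bool)])

    def group_samples(self, group: str, time: float | None = None) -> list[str]:
        """Sample names with the given group label (and time point, if given)."""
        mask = self.samples["group"] == group
        if time is not None:
            mask &= self.samples["time"] == time
        return list(self.samples.index[mask])

    def with_matrix(self, matrix: pd.DataFrame, detection_p=None) -> "ExpressionStudy":
        return ExpressionStudy(
            matrix=matrix,
            samples=self.samples.loc[list(matrix.columns)],
            detection_p=detection_p,
            name=self.name,
        )


@dataclass
class HomologMap:
    """Probe → gene maps per platform plus the cross-species gene pairing.

    ``probes_a`` / ``probes_b`` are two-column frames (``probe_id``,
    ``gene_id``); many probes may map to one gene, each probe to at most one.
    ``pairs`` is a two-column frame (``gene_a``, ``gene_b``).  One-to-many
    homolog relations are reduced to one-to-one deterministically by keeping,
    for every gene, the pair whose partner identifier sorts first.
    """

    probes_a: pd.DataFrame
    probes_b: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for attr, cols in (
            ("probes_a", ("probe_id", "gene_id")),
            ("probes_b", ("probe_id", "gene_id")),
            ("pairs", ("gene_a", "gene_b")),
        ):
            df = getattr(self, attr)
            if not set(cols) <= set(df.columns):
                raise ValueError(f"HomologMap.{attr} needs columns {cols}")
            df = df.loc[:, list(cols)].astype(str).reset_index(drop=True)
            setattr(self, attr, df)
        for attr in ("probes_a", "probes_b"):
            df = getattr(self, attr)
            if df["probe_id"].duplicated().any():
                raise ValueError(f"HomologMap.{attr}: a probe maps to several genes")
        self.pairs = self._reduce_one_to_one(self.pairs)

    @staticmethod
    def _reduce_one_to_one(pairs: pd.DataFrame) -> pd.DataFrame:
        pairs = pairs.sort_values(["gene_a", "gene_b"], kind="stable")
        pairs = pairs.drop_duplicates("gene_a", keep="first")
        pairs = pairs.drop_duplicates("gene_b", keep="first")
        return pairs.reset_index(drop=True)

    def probe_map(self, side: str) -> pd.DataFrame:
        if side not in ("a", "b"):
            raise ValueError("side must be 'a' or 'b'")
        return self.probes_a if side == "a" else self.probes_b


@dataclass
class MergedStudy:
    """The two gene-level matrices restricted to the shared homolog universe.

    Both matrices are indexed by the study-A gene identifier of each homolog
    pair (the common homolog key) in identical row order; ``m`` is the size of
    the shared universe.
    """

    matrix_a: pd.DataFrame
    matrix_b: pd.DataFrame
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.matrix_a.shape[0] != self.matrix_b.shape[0]:
            raise ValueError("merged matrices must have the same number of rows")
        if not self.matrix_a.index.equals(self.matrix_b.index):
            raise ValueError("merged matrices must share one row order")

    @property
    def m(self) -> int:
        return self.matrix_a.shape[0]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.matrix_a.index)

    def with_matrices(self, matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> "MergedStudy":
        return replace(self, matrix_a=matrix_a, matrix_b=matrix_b)
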