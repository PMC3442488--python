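"""Fisher's-exact over-representation analysis against a GMT collection.

Each gene set is tested with a one-sided (upper-tail) Fisher's exact test on
the 2×2 table (query ∩ set, query ∖ set, set ∖ query, neither) inside the
annotation universe; p-values are Benjamini–Hochberg adjusted across the
collection.  The report mirrors the usual over-representation table: set
name, hits, percent of mapped query genes, raw and adjusted p.  An optional
EASE variant (hits − 1 in the tail) is available for compatibility with
DAVID-style scores; the standard test is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .de_stats import bh_adjust

__all__ = ["GeneSetCollection", "fisher_enrichment", "read_gmt", "write_gmt"]


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {set name: (description, [gene ids])}."""
    out: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        out[name] = (desc, genes)
    return out


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    lines = [
        "\t".join([name, desc, *map(str, genes)])
        for name, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the annotation universe they induce."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        parsed = read_gmt(path)
        return cls(
            sets={name: frozenset(genes) for name, (_, genes) in parsed.items()},
            descriptions={name: desc for name, (desc, _) in parsed.items()},
        )

    def to_gmt(self, path) -> None:
        write_gmt(
            {
                name: (self.descriptions.get(name, ""), sorted(genes))
                for name, genes in self.sets.items()
            },
            path,
        )


def fisher_enrichment(
    query,
    collection: GeneSetCollection,
    background=None,
    ease: bool = False,
) -> pd.DataFrame:
    """Rank gene sets by one-sided Fisher's exact over-representation.

    The universe is the collection's annotation universe, intersected with
    ``background`` (e.g. all genes detected in the experiment) when supplied.
    ``percent`` is hits / (query genes mapped into the universe) × 100.  With
    ``ease=True`` one hit is discounted before taking the tail (the DAVID/EASE
    conservative variant).  Rows are sorted by raw p ascending.
    """
    query = {str(g) for g in query}
    universe = set(collection.universe)
    if background is not None:
        universe &= {str(g) for g in background}
    mapped_query = query & universe
    if not mapped_query:
        raise ValueError("fisher_enrichment: no query gene maps to the universe")
    n_uni = len(universe)
    n_query = len(mapped_query)
    rows = []
    for name, genes in collection.sets.items():
        genes_in_uni = genes & universe
        hits = len(mapped_query & genes_in_uni)
        tail_hits = max(hits - 1, 0) if ease else hits
        # P[X >= tail_hits], X ~ Hypergeom(n_uni, |set|, n_query)
        p = float(stats.hypergeom.sf(tail_hits - 1, n_uni, len(genes_in_uni), n_query))
        rows.append(
            {
                "set": name,
                "hits": hits,
                "set_size": len(genes_in_uni),
                "percent": 100.0 * hits / n_query,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    table.attrs["n_mapped_query"] = n_query
    table.attrs["n_universe"] = n_uni
    return table
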