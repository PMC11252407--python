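"""Reciprocal-best-BLAST-hit orthology and cross-list overlap statistics.

Orthologous gene pairs between two proteomes are inferred as reciprocal
best hits (RBH) from precomputed tabular BLAST output: for each query the
subject with the lowest e-value at or below a threshold (default 1e-10) is
its best hit, and a pair is an ortholog pair iff each member is the other's
best hit.  Gene-set overlaps and category enrichments are then computed on
translated sets with explicit reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "BLAST_COLUMNS",
    "parse_blast_tab",
    "best_hits",
    "rbh",
    "overlap_stats",
    "fisher_enrichment",
    "OverlapResult",
    "EnrichmentResult",
]

#: standard 12-column tabular BLAST (outfmt 6) layout
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def parse_blast_tab(path) -> pd.DataFrame:
    """Read outfmt-6 tabular BLAST output into a typed DataFrame.

    Rows with the wrong column count raise with the offending line number.
    An empty file yields an empty frame with the standard columns.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BLAST_COLUMNS)
    if df.shape[1] != len(BLAST_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(BLAST_COLUMNS)} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    df.columns = BLAST_COLUMNS

    def _to_float(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    for col in BLAST_COLUMNS[2:]:
        # round-trip-exact parsing (scientific notation e-values included)
        df[col] = df[col].map(_to_float)
    bad = df[list(BLAST_COLUMNS[2:])].isna().any(axis=1) | df["qseqid"].isna()
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:5]
        raise ValueError(f"{path}: malformed rows at lines {list(lines)}")
    if (df["evalue"] < 0).any() or (df["bitscore"] <= 0).any():
        raise ValueError(f"{path}: e-values must be >= 0 and bitscores > 0")
    return df


def _collapse_isoforms(ids: pd.Series, pattern: str) -> pd.Series:
    return ids.str.replace(pattern, "", regex=True)


def best_hits(
    hits: pd.DataFrame,
    emax: float = 1e-10,
    isoform_regex: str | None = None,
) -> dict[str, str]:
    """Best subject per query: lowest e-value at or below ``emax``.

    Ties at identical e-value are broken by higher bitscore, then by
    lexicographically smallest subject id, making the result independent of
    input row order.  ``isoform_regex`` optionally strips an isoform suffix
    from both id columns before ranking (best hit kept per collapsed gene).
    """
    if hits.empty:
        return {}
    df = hits[hits["evalue"] <= emax].copy()
    if df.empty:
        return {}
    if isoform_regex is not None:
        df["qseqid"] = _collapse_isoforms(df["qseqid"], isoform_regex)
        df["sseqid"] = _collapse_isoforms(df["sseqid"], isoform_regex)
    df = df.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    top = df.drop_duplicates("qseqid", keep="first")
    return dict(zip(top["qseqid"], top["sseqid"]))


def rbh(best_ab: dict[str, str], best_ba: dict[str, str]) -> set[tuple[str, str]]:
    """Reciprocal best hits: (a, b) iff best_ab[a] == b and best_ba[b] == a."""
    return {
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    }


@dataclass
class OverlapResult:
    n_query: int
    n_reference: int
    n_intersection: int
    percentage: float  # 100 * |∩| / |reference|, rounded to 2 decimals

    def __post_init__(self):
        if self.n_intersection > min(self.n_query, self.n_reference):
            raise ValueError("intersection larger than the smaller set")


def overlap_stats(
    query: set,
    reference: set,
    ortholog_map: dict[str, str] | None = None,
) -> OverlapResult:
    """Overlap of a query gene set with a reference set.

    When the sets live in different species, ``ortholog_map`` translates
    query ids into the reference namespace first (untranslatable genes
    cannot overlap).  The percentage is relative to the reference set and
    displayed to 2 decimals.
    """
    if not reference:
        raise ValueError("empty reference set")
    if not query:
        raise ValueError("empty query set")
    translated = (
        {ortholog_map[g] for g in query if g in ortholog_map}
        if ortholog_map is not None
        else set(query)
    )
    inter = translated & set(reference)
    pct = round(100.0 * len(inter) / len(reference), 2)
    return OverlapResult(len(query), len(reference), len(inter), pct)


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float


def fisher_enrichment(gene_list: set, category: set, universe: set) -> EnrichmentResult:
    """Two-sided Fisher's exact test for category enrichment in a list.

    The 2×2 table is (in list / not in list) × (in category / not), with
    margins taken over the declared universe; both the list and the
    category must be subsets of the universe.
    """
    universe = set(universe)
    gene_list, category = set(gene_list), set(category)
    if not gene_list <= universe:
        raise ValueError("gene list is not a subset of the universe")
    if not category <= universe:
        raise ValueError("category is not a subset of the universe")
    a = len(gene_list & category)
    b = len(gene_list - category)
    c = len(category - gene_list)
    d = len(universe) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(((a, b), (c, d)), float(p), float(odds))
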