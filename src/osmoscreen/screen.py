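"""Hit calling for pooled barcoded mutant screens.

The pipeline compares each insertional mutant's relative abundance after
competitive growth under an osmotic treatment to its relative abundance
after growth under a control condition (the phenotype ratio Φ), bins the
qualified alleles of each gene over a fixed 8-bin Φ grid, and asks — with an
exact conditional test on the resulting 2×8 contingency table — whether the
gene's allele phenotype distribution differs from that of all insertions in
the screen.  Gene-level p-values for genes with enough alleles are converted
to q-values with the Benjamini–Hochberg step-up procedure and hits are
called at a fixed FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PHI_BIN_EDGES",
    "N_BINS",
    "normalize_abundance",
    "compute_phi",
    "bin_phi",
    "gene_contingency",
    "GeneContingency",
    "fisher_gene_p",
    "bh_fdr",
    "call_hits",
    "run_screen_pipeline",
]

#: Interior edges of the 8 half-open phenotype bins:
#: (-inf, 0.0625), [0.0625, 0.125), [0.125, 0.25), [0.25, 0.5),
#: [0.5, 2.0), [2.0, 4.0), [4.0, 8.0), [8.0, 16.0) — with Φ ≥ 16 clipped
#: into the top bin.
PHI_BIN_EDGES = np.array([0.0625, 0.125, 0.25, 0.5, 2.0, 4.0, 8.0, 16.0])
N_BINS = 8

#: exact enumeration cap: compositions of n into 8 parts is C(n+7,7),
#: 50388 at n=12.
EXACT_ENUMERATION_CAP = 12

_REL_TOL = 1e-12  # tie tolerance for "probability <= observed"


def normalize_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert read counts to within-sample relative abundances.

    Each column is divided by its total so columns sum to 1; abundances are
    then comparable between libraries sequenced to different depths.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total reads: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    return counts / totals


def compute_phi(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    control: str,
    treatment: str,
    min_reads: int = 50,
    min_reads_on: str = "control",
) -> pd.DataFrame:
    """Compute per-allele phenotype ratios Φ for one control/treatment pair.

    Φ = (treatment relative abundance) / (control relative abundance).  A
    minimum read count (default 50) is required for the phenotype to be
    calculated; alleles below it are returned with ``qualified=False`` and
    Φ = NaN.  By default the minimum applies to the control sample — a low
    control count makes Φ unstable, while treatment dropout (the signal)
    must stay observable; ``min_reads_on`` may instead be ``"sum"`` or
    ``"both"``.
    """
    for s in (control, treatment):
        if s not in counts.columns:
            raise KeyError(f"sample {s!r} not in count matrix")
    if min_reads_on not in ("control", "treatment", "sum", "both"):
        raise ValueError(f"unknown min_reads_on mode {min_reads_on!r}")

    rel = normalize_abundance(counts[[control, treatment]])
    c, t = counts[control], counts[treatment]
    if min_reads_on == "control":
        qualified = c >= min_reads
    elif min_reads_on == "treatment":
        qualified = t >= min_reads
    elif min_reads_on == "sum":
        qualified = (c + t) >= min_reads
    else:
        qualified = (c >= min_reads) & (t >= min_reads)

    phi = np.where(qualified, rel[treatment] / rel[control], np.nan)
    out = pd.DataFrame(
        {
            "control_reads": c,
            "treatment_reads": t,
            "phi": phi,
            "qualified": qualified,
        },
        index=counts.index,
    )
    out = out.join(annotation[["gene_id", "allele_index"]], how="left")
    n_unmapped = int(out["gene_id"].isna().sum())
    if n_unmapped:
        logger.info("dropping %d unmapped barcodes", n_unmapped)
        out = out[out["gene_id"].notna()]
    return out


def bin_phi(phi) -> np.ndarray | int:
    """Map Φ values to bin indices 0..7 on the fixed half-open grid.

    Bins are closed on the left, open on the right; Φ ≥ 16 is clipped into
    the top bin (the printed edge list ends at 16).
    """
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0):
        raise ValueError("phi must be non-negative")
    idx = np.digitize(arr, PHI_BIN_EDGES, right=False)
    idx = np.minimum(idx, N_BINS - 1)
    return idx if arr.ndim else int(idx)


@dataclass
class GeneContingency:
    """A gene's qualified-allele Φ-bin counts paired with the screen-wide
    background table (the gene's own alleles included)."""

    gene_id: str
    gene_counts: np.ndarray  # length 8, sums to n_alleles
    background_counts: np.ndarray  # length 8, all qualified insertions

    @property
    def n_alleles(self) -> int:
        return int(self.gene_counts.sum())


def _bin_table(phenotypes: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    q = phenotypes[phenotypes["qualified"] & phenotypes["phi"].notna()].copy()
    q["bin"] = bin_phi(q["phi"].to_numpy())
    background = np.bincount(q["bin"], minlength=N_BINS)
    return q, background


def gene_contingency(phenotypes: pd.DataFrame, gene_id: str) -> GeneContingency:
    """Build the 2×8 contingency input for one gene.

    Counts the gene's qualified alleles per Φ bin and pairs them with the
    background vector over all qualified insertions in the screen.
    """
    q, background = _bin_table(phenotypes)
    gene_rows = q[q["gene_id"] == gene_id]
    if gene_rows.empty:
        raise ValueError(f"gene {gene_id!r} has no qualified alleles")
    gene_counts = np.bincount(gene_rows["bin"], minlength=N_BINS)
    return GeneContingency(gene_id, gene_counts, background)


# -- exact conditional test on the 2x8 table --------------------------------


@lru_cache(maxsize=64)
def _compositions(n: int, k: int = N_BINS) -> np.ndarray:
    """All length-k non-negative integer vectors summing to n (C(n+k-1,k-1) rows)."""
    if k == 1:
        return np.array([[n]], dtype=np.int64)
    blocks = []
    for first in range(n + 1):
        rest = _compositions(n - first, k - 1)
        col = np.full((rest.shape[0], 1), first, dtype=np.int64)
        blocks.append(np.hstack([col, rest]))
    return np.vstack(blocks)


def _log_hypergeom_pmf(tables: np.ndarray, background: np.ndarray) -> np.ndarray:
    """log P(gene row = x) under the multivariate hypergeometric null.

    P(x) = Π_j C(B_j, x_j) / C(N, n) with N = ΣB_j, n = Σx_j; margins fixed.
    Infeasible rows (x_j > B_j) get -inf.
    """
    x = np.atleast_2d(tables)
    B = np.asarray(background, dtype=np.int64)
    n = int(x[0].sum())
    N = int(B.sum())
    feasible = (x <= B).all(axis=1)
    logc = gammaln(B + 1)[None, :] - gammaln(x + 1) - gammaln(np.maximum(B - x, 0) + 1)
    logp = logc.sum(axis=1) - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    logp[~feasible] = -np.inf
    return logp


def _exact_fisher_p(gene: np.ndarray, background: np.ndarray) -> float:
    n = int(gene.sum())
    tables = _compositions(n)
    logp = _log_hypergeom_pmf(tables, background)
    obs = _log_hypergeom_pmf(gene[None, :], background)[0]
    if not np.isfinite(obs):
        raise ValueError("observed gene table infeasible for the given background")
    # two-sided exact-conditional p: total probability of outcomes no more
    # likely than the observed one (ties included, small relative tolerance)
    keep = logp <= obs + np.log1p(_REL_TOL)
    return float(min(1.0, np.exp(logp[keep]).sum()))


def _mc_fisher_p(
    gene: np.ndarray,
    background: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    n = int(gene.sum())
    draws = rng.multivariate_hypergeometric(
        np.asarray(background, dtype=np.int64), n, size=n_draws
    )
    logp = _log_hypergeom_pmf(draws, background)
    obs = _log_hypergeom_pmf(gene[None, :], background)[0]
    hits = int(np.sum(logp <= obs + np.log1p(_REL_TOL)))
    # add-one estimator keeps p > 0 and is standard for MC permutation p
    return (hits + 1) / (n_draws + 1)


def fisher_gene_p(
    table: GeneContingency,
    *,
    include_self: bool = True,
    exact_cap: int = EXACT_ENUMERATION_CAP,
    n_mc: int = 100_000,
    seed: int = 0,
    with_method: bool = False,
):
    """Two-sided exact conditional p for a gene's 2×8 phenotype table.

    The table compares the gene row against the background-minus-gene row
    with all margins fixed; under the null the gene row follows a
    multivariate hypergeometric law, and p is the total probability of all
    gene-row outcomes whose probability does not exceed the observed one.
    Exact enumeration is used for ``n_alleles <= exact_cap``; beyond it a
    seeded Monte-Carlo estimate over ``n_mc`` draws is returned and flagged
    (``with_method=True`` returns ``(p, method)``).

    ``include_self`` states whether ``table.background_counts`` already
    contains the gene's own alleles (the default, matching a background of
    *all* insertions in the screen).  When it does, the conditional urn is
    the background itself and the comparison row is background minus gene;
    when the background excludes the gene, the urn is background + gene.
    Either way the realized 2×8 table is gene row versus
    background-without-gene row with all margins fixed.
    """
    gene = np.asarray(table.gene_counts, dtype=np.int64)
    background = np.asarray(table.background_counts, dtype=np.int64)
    if background.sum() <= 0:
        raise ValueError("empty background table")
    urn = background if include_self else background + gene
    if (urn < gene).any():
        raise ValueError("gene counts exceed the background urn")
    n = int(gene.sum())
    if n < 1:
        raise ValueError("gene has no qualified alleles")
    if urn.sum() < n:
        raise ValueError("background smaller than the gene's allele count")

    if n <= exact_cap:
        p, method = _exact_fisher_p(gene, urn), "exact"
    else:
        rng = np.random.default_rng(seed)
        p, method = _mc_fisher_p(gene, urn, n_mc, rng), "monte-carlo"
    return (p, method) if with_method else p


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j)·m/j on the sorted p-values, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_hits(
    gene_stats: pd.DataFrame,
    fdr: float = 0.3,
    min_alleles: int = 3,
) -> pd.DataFrame:
    """Apply BH FDR and call hits.

    ``gene_stats`` needs columns ``gene_id, p, n_alleles``.  BH is applied
    only to genes with at least ``min_alleles`` qualified alleles (the
    screen requires more than 2); a gene is a hit iff its q-value is
    strictly below ``fdr``.
    """
    out = gene_stats.copy()
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["hit"] = pd.Series(dtype=bool)
        return out
    eligible = out["n_alleles"] >= min_alleles
    out["q"] = np.nan
    if eligible.any():
        out.loc[eligible, "q"] = bh_fdr(out.loc[eligible, "p"])
    out["hit"] = eligible & (out["q"] < fdr)
    return out


def run_screen_pipeline(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    design: Mapping[str, Mapping[str, str]],
    min_reads: int = 50,
    min_reads_on: str = "control",
    fdr: float = 0.3,
    min_alleles: int = 3,
    include_self: bool = True,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the full hit-calling pipeline, one HitTable per screen.

    ``design`` maps a screen name (condition/replicate) to
    ``{"control": <sample>, "treatment": <sample>}``.  Each screen is scored
    independently: Φ per allele, per-gene 2×8 contingency versus the
    screen-wide background, exact conditional p, BH within the screen.
    """
    results: dict[str, pd.DataFrame] = {}
    for screen_name, pair in design.items():
        if "control" not in pair or "treatment" not in pair:
            raise ValueError(f"design entry {screen_name!r} needs control and treatment")
        phen = compute_phi(
            counts, annotation, pair["control"], pair["treatment"],
            min_reads=min_reads, min_reads_on=min_reads_on,
        )
        q, background = _bin_table(phen)
        if q.empty:
            results[screen_name] = call_hits(
                pd.DataFrame(columns=["gene_id", "n_alleles", "p"]), fdr, min_alleles
            )
            continue
        rows = []
        # deterministic gene order regardless of input row order
        for gene_id, grp in sorted(q.groupby("gene_id"), key=lambda kv: kv[0]):
            gene_counts = np.bincount(grp["bin"], minlength=N_BINS)
            bg = background if include_self else background - gene_counts
            tab = GeneContingency(gene_id, gene_counts, bg)
            p, method = fisher_gene_p(
                tab, include_self=include_self, seed=seed, with_method=True
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_alleles": tab.n_alleles,
                    "p": p,
                    "p_method": method,
                }
            )
        stats = pd.DataFrame(rows)
        results[screen_name] = call_hits(stats, fdr=fdr, min_alleles=min_alleles)
    return results
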