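"""Tabular and image IO for the toolkit's standard file layouts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_design",
    "read_layout",
    "read_ratio_table",
    "read_gene_set",
    "write_tsv",
]

ANNOTATION_COLUMNS = ("gene_id", "allele_index")


def read_count_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a count TSV (barcode, gene_id, allele_index, one column/sample).

    Returns ``(counts, annotation)`` indexed by barcode.
    """
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    annotation = df[list(ANNOTATION_COLUMNS)]
    counts = df.drop(columns=list(ANNOTATION_COLUMNS))
    return counts, annotation


def write_count_table(path, counts: pd.DataFrame, annotation: pd.DataFrame) -> None:
    out = annotation.join(counts)
    out.to_csv(path, sep="\t", index_label="barcode")


def read_design(path) -> dict[str, dict[str, str]]:
    """YAML mapping screen name -> {control: sample, treatment: sample}."""
    with open(path) as fh:
        design = yaml.safe_load(fh)
    if not isinstance(design, dict):
        raise ValueError(f"{path}: design must be a mapping")
    for name, pair in design.items():
        if not isinstance(pair, dict) or {"control", "treatment"} - set(pair):
            raise ValueError(f"{path}: screen {name!r} needs control and treatment")
    return design


def read_layout(path) -> pd.DataFrame:
    """Plate layout CSV with columns row, col, genotype, is_wt[, excluded]."""
    df = pd.read_csv(path)
    needed = {"row", "col", "genotype", "is_wt"} - set(df.columns)
    if needed:
        raise ValueError(f"{path}: missing layout columns {sorted(needed)}")
    if "excluded" not in df.columns:
        df["excluded"] = False
    return df


def read_ratio_table(path) -> pd.DataFrame:
    """Phosphopeptide ratio TSV (peptide_id, protein_id, site, replicate,
    orientation, raw_ratio)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"peptide_id", "protein_id", "replicate", "orientation", "raw_ratio"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gene_set(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
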