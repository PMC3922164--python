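"""Readers and writers for every file format the pipeline touches.

The canonical on-disk dialect is tab-separated text with a header row
(GenePix-style spot tables are TSV-based); comma dialects are rejected rather
than guessed.  BLAST hit files use the standard headerless 12-column tabular
layout (``-outfmt 6``).  Gene lists are plain one-identifier-per-line files.
Identifier comparison everywhere is exact and case-sensitive: silent case
folding would create phantom orthologs.

Unknown extra columns are preserved on read but ignored by the pipeline.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from waspdom.synthdata import GROUPS

log = logging.getLogger(__name__)

SPOT_COLUMNS = ["array", "spot", "transcript", "fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5", "flag"]
SAMPLE_COLUMNS = ["sample", "group", "colony", "ovary_score", "wing_wear"]
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
COMPOUND_COLUMNS = ["wasp", "group", "colony", "compound", "concentration"]
EXPR_COLUMNS = ["transcript", "spot", "array", "channel", "sample", "value"]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", **kw)
    if df.shape[1] == 1 and "," in str(df.columns[0]):
        raise SchemaError(f"{path}: looks comma-separated; the expected dialect is TSV")
    return df


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, columns, path) -> None:
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), c]!r} "
                f"in column {c!r} at line {line}"
            )
        df[c] = coerced


# ---------------------------------------------------------------------------
# spot tables and sample sheets
# ---------------------------------------------------------------------------

def read_spot_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, SPOT_COLUMNS, path)
    _coerce_numeric(df, ["fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5", "flag"], path)
    for c in ("fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5"):
        if (df[c].dropna() < 0).any():
            raise SchemaError(f"{path}: negative intensity in column {c!r}")
    if df.duplicated(["array", "spot"]).any():
        raise SchemaError(f"{path}: duplicate (array, spot) rows")
    return df


def write_spot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, SAMPLE_COLUMNS, path)
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise SchemaError(
            f"{path}: group label(s) {sorted(df.loc[bad, 'group'].unique())} "
            f"outside the five groups {GROUPS}"
        )
    _coerce_numeric(df, ["ovary_score", "wing_wear"], path)
    if not df["ovary_score"].isin([1, 2, 3, 4]).all():
        raise SchemaError(f"{path}: ovary_score outside 1-4")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular, gene lists
# ---------------------------------------------------------------------------

def read_blast_tab(path) -> pd.DataFrame:
    """Read a headerless 12-column BLAST tabular (outfmt 6) file."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 12:
        raise SchemaError(f"{path}: expected >=12 tab-separated columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST_COLUMNS
    _coerce_numeric(df, ["pident", "length", "evalue", "bitscore"], path)
    if (df["evalue"] < 0).any():
        raise SchemaError(f"{path}: negative e-value")
    return df


def write_blast_tab(df: pd.DataFrame, path) -> None:
    df[BLAST_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_gene_list(path) -> set[str]:
    """One identifier per line; duplicates are collapsed (count logged)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    unique = set(ids)
    n_dup = len(ids) - len(unique)
    if n_dup:
        log.info("%s: collapsed %d duplicate identifier(s)", path, n_dup)
    return unique


def write_gene_list(ids, path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


# ---------------------------------------------------------------------------
# compound tables, expression tables, design
# ---------------------------------------------------------------------------

def read_compound_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, COMPOUND_COLUMNS, path)
    _coerce_numeric(df, ["concentration"], path)
    if (df["concentration"] < 0).any():
        raise SchemaError(f"{path}: negative concentration")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise SchemaError(f"{path}: unknown group label(s)")
    if df.duplicated(["wasp", "compound"]).any():
        raise SchemaError(f"{path}: duplicate (wasp, compound) rows")
    return df


def write_compound_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["array", "channel", "sample"], path)
    return df


def write_design(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, EXPR_COLUMNS, path)
    _coerce_numeric(df, ["value"], path)
    if not np.isfinite(df["value"]).all():
        raise SchemaError(f"{path}: non-finite expression values")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df[EXPR_COLUMNS].to_csv(path, sep="\t", index=False)
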