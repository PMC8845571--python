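"""Readers and writers for the standard plain-text inputs.

All readers accept TSV or CSV with a header row (delimiter inferred from the
extension).  The OTU-table reader auto-detects orientation (OTUs-as-rows vs
samples-as-rows) by id overlap with the metadata and always returns samples
as rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_otu_table", "read_taxonomy", "read_gene_table",
           "read_metadata"]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=_sep(path), index_col=0)
    if "pH" not in meta.columns:
        raise ValueError("metadata must contain a 'pH' column")
    return meta


def read_otu_table(path, metadata: pd.DataFrame | None = None,
                   orientation: str = "auto") -> pd.DataFrame:
    """Read a count table and return it with samples as rows.

    ``orientation`` is one of ``auto``, ``samples-as-rows`` or
    ``otus-as-rows``; ``auto`` requires metadata to compare id overlap.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "samples-as-rows":
        out = df
    elif orientation == "otus-as-rows":
        out = df.T
    elif orientation == "auto":
        if metadata is None:
            raise ValueError("orientation='auto' needs metadata for id overlap")
        ids = set(metadata.index.astype(str))
        row_hits = len(ids & set(df.index.astype(str)))
        col_hits = len(ids & set(df.columns.astype(str)))
        out = df if row_hits >= col_hits else df.T
        logger.info("read_otu_table: orientation resolved to %s",
                    "samples-as-rows" if row_hits >= col_hits else
                    "otus-as-rows")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if (out.to_numpy() < 0).any():
        raise ValueError("count table contains negative entries")
    out.index.name = "sample"
    out.columns.name = None
    return out


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep=_sep(path), index_col=0)
    if "genus" not in tax.columns:
        raise ValueError("taxonomy must contain a 'genus' column")
    return tax


def read_gene_table(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep=_sep(path), index_col=0)
    for col in ("category", "source_genus"):
        if col not in genes.columns:
            raise ValueError(f"gene table must contain a {col!r} column")
    bad = set(genes["category"]) - {"al_resistance", "antioxidant"}
    if bad:
        raise ValueError(f"unknown gene categories: {sorted(bad)}")
    return genes
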