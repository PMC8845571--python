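"""Community table preparation: rarefaction, tolerant-taxon identification
from functional-gene source organisms, and diversity summaries.

The universal community object is a pandas DataFrame of non-negative integer
counts with samples as rows and OTUs as columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "identify_tolerant", "alpha_diversity", "bray_curtis"]


def rarefy(table: pd.DataFrame, depth: int, seed: int | None = 0) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement.

    Draws are multivariate hypergeometric, i.e. exactly the distribution of
    subsampling ``depth`` reads from the observed ones, so every rarefied
    count is bounded by the original and the per-sample total is exactly
    ``depth``.  Samples with fewer than ``depth`` reads are dropped (logged),
    never padded.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be a positive integer")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = table.index[~keep]
    if len(dropped):
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, list(dropped[:10]))
    rows = []
    for _, counts in table.loc[keep].iterrows():
        c = counts.to_numpy(dtype=np.int64)
        rows.append(rng.multivariate_hypergeometric(c, depth, method="marginals"))
    out = pd.DataFrame(np.asarray(rows, dtype=np.int64) if rows else
                       np.empty((0, table.shape[1]), dtype=np.int64),
                       index=table.index[keep], columns=table.columns)
    return out


def identify_tolerant(taxonomy: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Identify putatively Al-tolerant OTUs from gene source organisms.

    The source-organism genera of every ``al_resistance`` probe form the
    reference pool; an OTU is tolerant-eligible when its genus matches one of
    them exactly after trimming and case-folding.  OTUs with a missing genus
    are never eligible.
    """
    al_rows = genes.loc[genes["category"] == "al_resistance"]
    pool = {str(g).strip().casefold() for g in al_rows["source_genus"].dropna()}
    pool.discard("")
    if not pool:
        logger.warning("identify_tolerant: no al_resistance source genera; "
                       "returning empty set")
        return set()
    genus = taxonomy["genus"].fillna("").astype(str).str.strip().str.casefold()
    hits = genus.index[genus.isin(pool) & (genus != "")]
    return set(hits)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness (observed OTUs) and Shannon index in nats.

    Shannon is -sum(p ln p) over the nonzero proportions of each sample;
    all-zero samples get richness 0 and Shannon 0.
    """
    if table.shape[0] == 0:
        raise ValueError("alpha_diversity: empty table")
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    shannon = np.zeros(len(table))
    for s in range(len(table)):
        if totals[s] <= 0:
            logger.info("alpha_diversity: all-zero sample %s", table.index[s])
            continue
        p = counts[s][counts[s] > 0] / totals[s]
        shannon[s] = -(p * np.log(p)).sum()
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=table.index)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity matrix.

    BC(u, v) = sum|u - v| / sum(u + v), equivalently 1 - 2 W / (sum u + sum v)
    with W the shared abundance.
    """
    if table.shape[0] < 2:
        raise ValueError("bray_curtis needs at least two samples")
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero samples are identical
    return pd.DataFrame(d, index=table.index, columns=table.index)
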