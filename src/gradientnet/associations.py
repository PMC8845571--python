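"""Gene-taxon association networks and matrix-correlation (Mantel) tests.

Bipartite networks connect functional-gene probes to taxa whose abundance
profiles they track: an edge requires a strong (Spearman r > 0.6) and
significant (BH-FDR q < 0.01) rank correlation over the shared samples.
Simple and partial Mantel tests relate community dissimilarity matrices to
gene-profile or environmental distance matrices by permutation.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_fdr_network",
    "MantelResult",
    "mantel",
    "partial_mantel",
    "fit_exponential_decay",
]


def _gene_signal_matrix(genes: pd.DataFrame) -> pd.DataFrame:
    """Probe x sample signal block of a gene table (non-annotation columns)."""
    meta_cols = [c for c in ("family", "category", "source_genus")
                 if c in genes.columns]
    return genes.drop(columns=meta_cols)


def spearman_fdr_network(
    genes: pd.DataFrame,
    table: pd.DataFrame,
    r_threshold: float = 0.6,
    q_threshold: float = 0.01,
    absolute: bool = False,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Thresholded gene-taxon Spearman network.

    Spearman r (average-rank ties) is computed for every gene x taxon pair
    over the shared samples; two-sided p-values (t approximation) are
    corrected by Benjamini-Hochberg across all tested pairs jointly; an edge
    requires r > r_threshold (|r| with ``absolute``) and q < q_threshold.
    Pairs involving a constant vector are skipped with a warning.

    Returns the edge table (gene, taxon, r, p, q) and the bipartite graph.
    """
    sig = _gene_signal_matrix(genes)
    shared = [s for s in sig.columns if s in table.index]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples between the gene "
                         "table and the OTU table")
    G = sig[shared].to_numpy(dtype=float)        # probes x samples
    X = table.loc[shared].to_numpy(dtype=float)  # samples x taxa
    n = len(shared)

    g_const = np.ptp(G, axis=1) == 0
    t_const = np.ptp(X, axis=0) == 0
    if g_const.any() or t_const.any():
        warnings.warn(
            f"skipping {int(g_const.sum())} constant gene and "
            f"{int(t_const.sum())} constant taxon vectors", UserWarning,
            stacklevel=2)

    g_ranks = stats.rankdata(G, axis=1)
    x_ranks = stats.rankdata(X, axis=0)
    gz = (g_ranks - g_ranks.mean(axis=1, keepdims=True))
    xz = (x_ranks - x_ranks.mean(axis=0, keepdims=True))
    g_norm = np.sqrt((gz ** 2).sum(axis=1))
    x_norm = np.sqrt((xz ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (gz @ xz) / np.outer(g_norm, x_norm)   # probes x taxa

    probes = list(sig.index)
    taxa = list(table.columns)
    rows = []
    for gi, ti in itertools.product(range(len(probes)), range(len(taxa))):
        if g_const[gi] or t_const[ti]:
            continue
        r = float(np.clip(R[gi, ti], -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
        rows.append((probes[gi], taxa[ti], r, p))
    edges = pd.DataFrame(rows, columns=["gene", "taxon", "r", "p"])
    if edges.empty:
        return edges.assign(q=[]), nx.Graph()
    edges["q"] = multipletests(edges["p"], method="fdr_bh")[1]

    strength = edges["r"].abs() if absolute else edges["r"]
    keep = (strength > r_threshold) & (edges["q"] < q_threshold)
    kept = edges.loc[keep].reset_index(drop=True)

    net = nx.Graph()
    net.add_nodes_from(kept["gene"].unique(), bipartite="gene")
    net.add_nodes_from(kept["taxon"].unique(), bipartite="taxon")
    for _, row in kept.iterrows():
        net.add_edge(row["gene"], row["taxon"], r=row["r"], q=row["q"])
    return kept, net


@dataclass
class MantelResult:
    r: float
    pvalue: float
    n_perm: int
    flavor: str  # "simple" | "partial"


def _tri(d: np.ndarray) -> np.ndarray:
    return d[np.tril_indices_from(d, k=-1)]


def _check_distance(d, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = math.sqrt((u @ u) * (v @ v))
    if denom == 0:
        raise ValueError("constant distance matrix")
    return float((u @ v) / denom)


def mantel(
    d1,
    d2,
    n_perm: int | str = 9999,
    seed: int | None = 0,
) -> MantelResult:
    """Simple Mantel test: Pearson correlation of two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries; the
    one-sided (greater) p-value comes from jointly permuting the row/column
    labels of ``d2``, with the add-one convention.  ``n_perm="exact"``
    enumerates all label permutations instead (small n only).
    """
    d1 = _check_distance(d1, "d1")
    d2 = _check_distance(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have identical shape")
    n = d1.shape[0]
    u = _tri(d1)
    r_obs = _pearson(u, _tri(d2))

    if n_perm == "exact":
        perms = list(itertools.permutations(range(n)))
        count = sum(
            _pearson(u, _tri(d2[np.ix_(p, p)])) >= r_obs - 1e-12
            for p in perms)
        return MantelResult(r_obs, count / len(perms), len(perms), "simple")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        p = rng.permutation(n)
        if _pearson(u, _tri(d2[np.ix_(p, p)])) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + int(n_perm)), int(n_perm),
                        "simple")


def partial_mantel(
    d1,
    d2,
    d3,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> MantelResult:
    """Partial Mantel test of (d1, d2) controlling for d3.

    The lower-triangle vectors of d1 and d2 are each residualised on d3 by
    ordinary least squares and the partial r is the Pearson correlation of
    the residuals.  The p-value permutes the labels of d2 (one-sided,
    greater, add-one).
    """
    d1 = _check_distance(d1, "d1")
    d2 = _check_distance(d2, "d2")
    d3 = _check_distance(d3, "d3")
    if not (d1.shape == d2.shape == d3.shape):
        raise ValueError("distance matrices must have identical shape")
    n = d1.shape[0]
    w = _tri(d3)

    def residual(v):
        Xd = np.column_stack([np.ones_like(w), w])
        beta, *_ = np.linalg.lstsq(Xd, v, rcond=None)
        return v - Xd @ beta

    def safe_corr(u, v, v_raw):
        # residualising a matrix on (a copy of) itself leaves numerical dust;
        # treat a vanishing residual as zero partial correlation
        if np.sum(v ** 2) < 1e-20 * max(np.sum(v_raw ** 2), 1.0):
            return 0.0
        return _pearson(u, v)

    u_res = residual(_tri(d1))
    v_raw = _tri(d2)
    r_obs = safe_corr(u_res, residual(v_raw), v_raw)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        p = rng.permutation(n)
        w_raw = _tri(d2[np.ix_(p, p)])
        if safe_corr(u_res, residual(w_raw), w_raw) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + int(n_perm)), int(n_perm),
                        "partial")


def fit_exponential_decay(x, y) -> tuple[float, float, float]:
    """Fit y = a * exp(-b * x) by nonlinear least squares.

    Initialised from the log-linear fit on the positive y values; R^2 is
    computed on the original scale.  Falls back to the log-linear estimate
    (with a warning) when the nonlinear fit does not converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired observations")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    pos = y > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 positive y values")
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    a0, b0 = math.exp(intercept), -slope

    def model(xv, a, b):
        return a * np.exp(-b * xv)

    try:
        (a, b), _ = optimize.curve_fit(model, x, y, p0=(a0, b0), maxfev=5000)
    except RuntimeError:
        warnings.warn("exponential fit did not converge; using the "
                      "log-linear estimate", UserWarning, stacklevel=2)
        a, b = a0, b0
    resid = y - model(x, a, b)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return float(a), float(b), float(r2)
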