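"""Levins niche breadth, community-level Bcom per role and pH bin, and
multiple-range significance groupings (Duncan / Tukey letters).

Levins' index B = 1 / sum_i P_i^2 measures the effective number of habitats
(communities) an OTU occupies: B = 1 for a single-habitat specialist, B = N
for an OTU spread evenly over all N communities of the metacommunity.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["levins_b", "niche_breadth_table", "bcom", "range_groups",
           "DEFAULT_PH_BINS", "assign_ph_bins"]

#: default metacommunity bins along the pH gradient
DEFAULT_PH_BINS = (5.1, 7.0)
PH_BIN_LABELS = ("pH<5.1", "5.1<pH<7", "pH>7")


def levins_b(p: np.ndarray) -> float:
    """Levins niche breadth B = 1 / sum(p^2) of a proportion vector.

    Non-negative inputs that do not sum to one are renormalised (logged),
    so B is invariant to positive rescaling.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < 0):
        raise ValueError("p must be a 1-D non-negative vector")
    total = p.sum()
    if total <= 0:
        raise ValueError("undefined niche: all-zero proportion vector")
    if not np.isclose(total, 1.0):
        logger.debug("levins_b: renormalising vector with sum %.4g", total)
        p = p / total
    return float(1.0 / np.sum(p ** 2))


def assign_ph_bins(meta: pd.DataFrame,
                   edges: tuple[float, ...] = DEFAULT_PH_BINS) -> pd.Series:
    """Label each sample with its pH bin (default: <5.1, 5.1-7, >7)."""
    cut = [-np.inf, *edges, np.inf]
    labels = PH_BIN_LABELS if edges == DEFAULT_PH_BINS else [
        f"bin{k}" for k in range(len(cut) - 1)]
    return pd.cut(meta["pH"], bins=cut, labels=labels,
                  right=False).astype(str)


def niche_breadth_table(table: pd.DataFrame, bins: pd.Series,
                        members: set[str] | None = None) -> pd.DataFrame:
    """Per-OTU Levins B within each pH bin (the metacommunity).

    ``P_ij`` is OTU j's abundance in sample i divided by its total over the
    bin's samples.  OTUs absent from a bin are excluded there (logged).
    Returns a tidy frame (otu, bin, B, n_samples).
    """
    cols = sorted(members & set(table.columns)) if members is not None \
        else list(table.columns)
    rows = []
    excluded = 0
    for label in pd.unique(bins):
        samples = bins.index[bins == label]
        sub = table.loc[table.index.intersection(samples), cols]
        if sub.empty:
            continue
        counts = sub.to_numpy(dtype=float)
        totals = counts.sum(axis=0)
        for k, otu in enumerate(cols):
            if totals[k] <= 0:
                excluded += 1
                continue
            b = levins_b(counts[:, k] / totals[k])
            rows.append((otu, label, b, len(sub)))
    if excluded:
        logger.info("niche_breadth_table: excluded %d (otu, bin) cells with "
                    "no occurrences", excluded)
    return pd.DataFrame(rows, columns=["otu", "bin", "B", "n_samples"])


def bcom(table: pd.DataFrame, members: set[str], bins: pd.Series) -> pd.DataFrame:
    """Community-level niche breadth: mean member B per pH bin.

    Returns one row per bin with the mean, sd and member count of the Levins
    B values of the members present in that bin.
    """
    if not members:
        raise ValueError("bcom requires a non-empty member set")
    per_otu = niche_breadth_table(table, bins, members=members)
    agg = per_otu.groupby("bin")["B"].agg(["mean", "std", "count"])
    return agg.rename(columns={"mean": "bcom", "std": "sd",
                               "count": "n_members"}).reset_index()


# ---------------------------------------------------------------------------
# multiple-range letter groupings

def _letter_assignment(n_groups: int, nonsig: set[tuple[int, int]]) -> list[str]:
    """Compact letter display from a pairwise not-different relation over
    groups sorted by mean.  Maximal intervals of mutually non-different
    groups share a letter; every group gets at least one."""
    intervals = []
    for i in range(n_groups):
        j = i
        while j + 1 < n_groups and all(
                (a, b) in nonsig
                for a, b in itertools.combinations(range(i, j + 2), 2)):
            j += 1
        intervals.append((i, j))
    # drop intervals nested in an earlier one
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                   for o in intervals):
            maximal.append(iv)
    letters = [""] * n_groups
    for rank, (lo, hi) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + rank)
        for g in range(lo, hi + 1):
            letters[g] += ch
    return letters


def range_groups(values: dict[str, np.ndarray], alpha: float = 0.05,
                 method: str = "duncan") -> pd.DataFrame:
    """One-way ANOVA followed by a multiple-range letter grouping.

    ``duncan`` uses Duncan's multiple range test: the range of k adjacent
    ordered means is significant when it exceeds
    ``q_{1-(1-alpha)^(k-1)}(k, df) * sqrt(MSE / n_h)`` (studentized-range
    critical values at the stepwise protection levels, harmonic mean group
    size), with non-significant ranges protecting their sub-ranges.
    ``tukey`` uses Tukey's HSD on all pairs.  Groups sharing a letter are
    not significantly different.  Letters are assigned on groups sorted by
    descending mean.
    """
    names = list(values)
    if len(names) < 2 or any(len(np.asarray(values[g])) < 2 for g in names):
        raise ValueError("range_groups needs >= 2 groups with >= 2 values")
    arrays = {g: np.asarray(values[g], dtype=float) for g in names}
    ns = {g: len(a) for g, a in arrays.items()}
    means = {g: a.mean() for g, a in arrays.items()}
    df_err = sum(ns.values()) - len(names)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err
    if mse <= 0:
        raise ValueError("degenerate data: zero within-group variance "
                         "everywhere")

    order = sorted(names, key=lambda g: means[g], reverse=True)
    m = np.array([means[g] for g in order])
    k_groups = len(order)

    nonsig: set[tuple[int, int]] = set()
    if method == "duncan":
        n_h = k_groups / sum(1.0 / ns[g] for g in order)
        se = np.sqrt(mse / n_h)
        protected = set()
        for span in range(k_groups, 1, -1):
            p_level = (1.0 - alpha) ** (span - 1)
            q_crit = stats.studentized_range.ppf(p_level, span, df_err)
            for i in range(k_groups - span + 1):
                j = i + span - 1
                if (i, j) in protected:
                    continue
                if m[i] - m[j] <= q_crit * se:
                    for a, b in itertools.combinations(range(i, j + 1), 2):
                        protected.add((a, b))
                        nonsig.add((a, b))
    elif method == "tukey":
        q_crit = stats.studentized_range.ppf(1.0 - alpha, k_groups, df_err)
        for i, j in itertools.combinations(range(k_groups), 2):
            gi, gj = order[i], order[j]
            se_pair = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            if abs(means[gi] - means[gj]) <= q_crit * se_pair:
                nonsig.add((i, j))
    else:
        raise ValueError(f"unknown method {method!r}")

    letters = _letter_assignment(k_groups, nonsig)
    return pd.DataFrame({
        "group": order,
        "mean": m,
        "n": [ns[g] for g in order],
        "letters": letters,
    }).set_index("group")
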