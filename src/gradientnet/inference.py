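"""Directed interaction inference under the Ricker model.

The community is assumed to follow discrete Ricker dynamics

    x_i(t+1) = x_i(t) * exp(r_i + sum_j A_ij x_j(t) + eps_i(t))

so that the log-ratio y_i(t) = ln x_i(t+1) - ln x_i(t) is linear in the
community state.  ``RickerInteractionModel`` estimates the sparse signed
matrix A by forward stepwise ridge regression with bagging over random
half-splits of the step axis (a LIMITS-style procedure): for each target
taxon the self term is always in the model, predictors enter one at a time
while they reduce the held-out error by a relative margin, and an entry is
kept only when selected in at least half of the bags, with the median of the
bagged estimates as the final value.

The nonzero off-diagonal entries of A form a directed network (A_ij != 0 is
an edge j -> i), from which each taxon receives a role: influential
(out-edges only), sensitive (in-edges only), bidirectional (both) or orphan
(neither).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .community import alpha_diversity
from .series import PhSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RickerInteractionModel",
    "InteractionMatrix",
    "infer_limits",
    "link_count_significance",
    "to_network",
    "classify_roles",
    "role_diversity",
]

ROLES = ("influential", "sensitive", "bidirectional", "orphan")


@dataclass
class InteractionMatrix:
    """Fitted interaction structure: A[i, j] is the effect of taxon j on i."""

    taxa: list[str]
    A: np.ndarray
    r: np.ndarray
    prediction_error: np.ndarray
    pseudocount: float

    def sparsity(self) -> float:
        off = self.A.copy()
        np.fill_diagonal(off, 0.0)
        n = len(self.taxa)
        return float((off != 0).sum() / max(n * (n - 1), 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.taxa, columns=self.taxa)


def _ridge_path_fit(Z, y, lam):
    """Ridge solve on standardized predictors; returns coefficients."""
    n, k = Z.shape
    G = Z.T @ Z + lam * n * np.eye(k)
    return np.linalg.solve(G, Z.T @ y)


class RickerInteractionModel(BaseEstimator):
    """Sparse Ricker interaction inference by bagged forward stepwise ridge.

    Parameters
    ----------
    ridge_lambda : float
        Ridge penalty relative to standardized predictors.
    bag_iters : int
        Number of random half-splits of the transition axis.
    error_threshold : float
        Minimal relative reduction of held-out MSE for a predictor to enter.
    keep_fraction : float
        Minimal fraction of bags a predictor must be selected in to survive
        aggregation.
    pseudocount : float or None
        Added to abundances before logs; ``None`` uses half the smallest
        nonzero value of the fitted data when zeros are present, else 0.
    random_state : int or None
        Seed for the bagging splits.

    Attributes
    ----------
    interaction_matrix_ : ndarray of shape (n_taxa, n_taxa)
        Median bagged estimates; entry (i, j) is the effect of j on i.
    growth_rates_ : ndarray of shape (n_taxa,)
    prediction_error_ : ndarray of shape (n_taxa,)
        Median held-out MSE per target taxon.
    selection_frequency_ : ndarray of shape (n_taxa, n_taxa)
        Fraction of bags each predictor was selected in.
    """

    def __init__(self, ridge_lambda: float = 0.01, bag_iters: int = 31,
                 error_threshold: float = 0.05, keep_fraction: float = 0.5,
                 pseudocount: float | None = None,
                 random_state: int | None = 0):
        self.ridge_lambda = ridge_lambda
        self.bag_iters = bag_iters
        self.error_threshold = error_threshold
        self.keep_fraction = keep_fraction
        self.pseudocount = pseudocount
        self.random_state = random_state

    # X follows the sklearn convention: rows are steps, columns are taxa.
    def fit(self, X, y=None, pair_mask=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be a (steps, taxa) matrix with >= 2 taxa")
        n_steps, n_taxa = X.shape
        if n_steps < 8:
            raise ValueError("insufficient data: need at least 8 steps")
        if n_steps < 3 * n_taxa:
            warnings.warn(
                f"series has {n_steps} steps for {n_taxa} taxa; at least "
                f"{3 * n_taxa} recommended", UserWarning, stacklevel=2)
        if np.any(X < 0):
            raise ValueError("abundances must be non-negative")
        pc = self.pseudocount
        if pc is None:
            nz = X[X > 0]
            if nz.size == 0:
                raise ValueError("all-zero series")
            # pseudocount is only needed when zeros occur; half the smallest
            # nonzero value keeps the log-ratios defined without dominating
            pc = float(nz.min() / 2.0) if np.any(X == 0) else 0.0
        if pc <= 0 and np.any(X == 0):
            raise ValueError("zero abundances require a positive pseudocount")
        Xp = X + pc

        L = np.log(Xp)
        Y = L[1:] - L[:-1]                  # (T-1, taxa) log-ratios
        P = Xp[:-1]                         # predictors: state at t
        if pair_mask is not None:
            pair_mask = np.asarray(pair_mask, dtype=bool)
            if pair_mask.shape != (n_steps - 1,):
                raise ValueError("pair_mask must have length n_steps - 1")
            Y, P = Y[pair_mask], P[pair_mask]
        T = len(Y)
        if T < 8:
            raise ValueError("insufficient data: fewer than 8 usable "
                             "transitions")

        rng = np.random.default_rng(self.random_state)
        half = T // 2
        splits = [rng.permutation(T) for _ in range(self.bag_iters)]

        A_est = np.zeros((n_taxa, n_taxa))
        sel_freq = np.zeros((n_taxa, n_taxa))
        r_est = np.zeros(n_taxa)
        err_est = np.zeros(n_taxa)

        for i in range(n_taxa):
            y_i = Y[:, i]
            bag_coefs: list[dict[int, float]] = []
            bag_r: list[float] = []
            bag_err: list[float] = []
            for perm in splits:
                tr, te = perm[:half], perm[half:]
                coefs, r0, err = self._stepwise(P, y_i, tr, te, i)
                bag_coefs.append(coefs)
                bag_r.append(r0)
                bag_err.append(err)
            r_est[i] = float(np.median(bag_r))
            err_est[i] = float(np.median(bag_err))
            for j in range(n_taxa):
                picked = [c[j] for c in bag_coefs if j in c]
                sel_freq[i, j] = len(picked) / self.bag_iters
                if j == i:
                    # self term is always in the model; median over all bags
                    A_est[i, j] = float(np.median([c.get(j, 0.0)
                                                   for c in bag_coefs]))
                elif len(picked) >= self.keep_fraction * self.bag_iters:
                    A_est[i, j] = float(np.median(picked))

        self.n_features_in_ = n_taxa
        self.pseudocount_ = pc
        self.interaction_matrix_ = A_est
        self.growth_rates_ = r_est
        self.prediction_error_ = err_est
        self.selection_frequency_ = sel_freq
        return self

    def _stepwise(self, P, y, tr, te, self_idx):
        """Forward stepwise ridge for one target on one bag.

        Returns (coefficients on the original scale keyed by predictor
        index, intercept, held-out MSE of the final model).
        """
        mu = P[tr].mean(axis=0)
        sd = P[tr].std(axis=0)
        usable = sd > 0
        n_taxa = P.shape[1]

        def fit_eval(active):
            cols = [j for j in active if usable[j]]
            ytr = y[tr]
            if not cols:
                pred_te = np.full(len(te), ytr.mean())
                return {}, float(ytr.mean()), float(
                    np.mean((y[te] - pred_te) ** 2))
            Ztr = (P[np.ix_(tr, cols)] - mu[cols]) / sd[cols]
            beta = _ridge_path_fit(Ztr, ytr - ytr.mean(), self.ridge_lambda)
            b_orig = beta / sd[cols]
            intercept = ytr.mean() - float(mu[cols] @ b_orig)
            pred_te = intercept + P[np.ix_(te, cols)] @ b_orig
            err = float(np.mean((y[te] - pred_te) ** 2))
            return dict(zip(cols, b_orig)), intercept, err

        active = [self_idx]
        coefs, intercept, err = fit_eval(active)
        while len(active) < n_taxa:
            if err <= 1e-14:
                break
            best_j, best = None, (None, None, err)
            for j in range(n_taxa):
                if j in active or not usable[j]:
                    continue
                cand = fit_eval(active + [j])
                if cand[2] < best[2]:
                    best_j, best = j, cand
            if best_j is None:
                break
            if (err - best[2]) / err < self.error_threshold:
                break
            active.append(best_j)
            coefs, intercept, err = best
        return coefs, intercept, err


def infer_limits(
    series: PhSeries | np.ndarray,
    ridge_lambda: float = 0.01,
    bag_iters: int = 31,
    error_threshold: float = 0.05,
    seed: int | None = 0,
    pseudocount: float | None = None,
    exclude_interpolated: bool = False,
    keep_fraction: float = 0.5,
) -> InteractionMatrix:
    """Infer the signed interaction matrix from a pH pseudo-series.

    Thin wrapper over :class:`RickerInteractionModel`.  Interpolated steps
    participate in the regression by default — a survey rarely observes every
    0.01-pH step, and dropping every transition that touches a filled step
    discards most of the series; ``exclude_interpolated=True`` restricts the
    fit to transitions between consecutively observed steps instead.
    """
    if isinstance(series, PhSeries):
        X = series.values.T
        taxa = list(series.taxa)
        pair_mask = None
        if exclude_interpolated and series.interpolated.any():
            obs = ~series.interpolated
            pair_mask = obs[:-1] & obs[1:]
    else:
        X = np.asarray(series, dtype=float).T
        taxa = [f"taxon_{k}" for k in range(X.shape[1])]
        pair_mask = None
    model = RickerInteractionModel(
        ridge_lambda=ridge_lambda, bag_iters=bag_iters,
        error_threshold=error_threshold, keep_fraction=keep_fraction,
        pseudocount=pseudocount, random_state=seed,
    ).fit(X, pair_mask=pair_mask)
    return InteractionMatrix(
        taxa=taxa,
        A=model.interaction_matrix_,
        r=model.growth_rates_,
        prediction_error=model.prediction_error_,
        pseudocount=model.pseudocount_,
    )


def link_count_significance(
    A: InteractionMatrix | np.ndarray,
    n_rand: int = 100,
    seed: int | None = 0,
    statistic: str = "non_orphan",
) -> float:
    """Permutation significance of the inferred link structure.

    The nonzero off-diagonal entries are repeatedly rethrown to uniformly
    random off-diagonal positions (preserving their number and values) and
    the chosen statistic — the number of non-orphan taxa (default) or the
    edge count — recomputed; p = (1 + #{random >= observed}) / (1 + n_rand).
    """
    M = A.A if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)
    n = M.shape[0]
    off = M.copy()
    np.fill_diagonal(off, 0.0)
    vals = off[off != 0]
    if vals.size == 0:
        warnings.warn("all-zero interaction matrix; p = 1", UserWarning,
                      stacklevel=2)
        return 1.0

    def stat(mat):
        if statistic == "edges":
            return int((mat != 0).sum())
        nz = mat != 0
        return int(np.count_nonzero(nz.any(axis=0) | nz.any(axis=1)))

    observed = stat(off)
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_rand):
        rand = np.zeros_like(off)
        picks = rng.choice(len(slots), size=vals.size, replace=False)
        for v, k in zip(vals, picks):
            rand[slots[k]] = v
        if stat(rand) >= observed:
            count += 1
    return (1 + count) / (1 + n_rand)


def to_network(A: InteractionMatrix | np.ndarray,
               magnitude_floor: float = 0.0,
               taxa: list[str] | None = None) -> nx.DiGraph:
    """Directed network of the off-diagonal entries of A.

    Emits one edge j -> i per entry with |A_ij| > magnitude_floor; self
    terms (density dependence) never become edges.  Edge attributes:
    ``weight`` (the entry) and ``sign`` ("+" or "-").
    """
    if isinstance(A, InteractionMatrix):
        M, names = A.A, A.taxa
    else:
        M = np.asarray(A, dtype=float)
        names = taxa or [f"taxon_{k}" for k in range(M.shape[0])]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("interaction matrix must be square")
    g = nx.DiGraph()
    g.add_nodes_from(names)
    n = M.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and abs(M[i, j]) > magnitude_floor:
                g.add_edge(names[j], names[i], weight=float(M[i, j]),
                           sign="+" if M[i, j] > 0 else "-")
    return g


def classify_roles(net: nx.DiGraph) -> pd.DataFrame:
    """Per-taxon role from in-/out-degree of the directed network.

    influential: out-degree only; sensitive: in-degree only; bidirectional:
    both; orphan: neither (retained in the table, flagged by the label).
    """
    rows = []
    for node in net.nodes:
        ind, outd = net.in_degree(node), net.out_degree(node)
        if outd > 0 and ind == 0:
            role = "influential"
        elif ind > 0 and outd == 0:
            role = "sensitive"
        elif ind > 0 and outd > 0:
            role = "bidirectional"
        else:
            role = "orphan"
        rows.append((node, ind, outd, role))
    return pd.DataFrame(rows, columns=["taxon", "in_degree", "out_degree",
                                       "role"]).set_index("taxon")


def role_diversity(table: pd.DataFrame, roles: pd.DataFrame) -> pd.DataFrame:
    """Alpha diversity and relative abundance of each role's OTU subset.

    Returns a tidy frame with one row per (sample, role): richness and
    Shannon restricted to the role members, and the members' share of the
    sample's total reads.
    """
    totals = table.sum(axis=1)
    out = []
    for role in ROLES:
        members = [t for t in roles.index[roles["role"] == role]
                   if t in table.columns]
        if not members:
            logger.warning("role_diversity: no taxa with role %r", role)
            continue
        sub = table[members]
        alpha = alpha_diversity(sub)
        rel = sub.sum(axis=1) / totals.replace(0, np.nan)
        for sample in table.index:
            out.append((sample, role, alpha.loc[sample, "richness"],
                        alpha.loc[sample, "shannon"],
                        float(np.nan_to_num(rel.loc[sample]))))
    return pd.DataFrame(out, columns=["sample", "role", "richness",
                                      "shannon", "relative_abundance"])
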