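"""Dynamics diagnostics on the pH pseudo-series: per-taxon noise color from
the periodogram slope, and a permutation screen for neutral (structure-free)
dynamics.

Noise color summarises how strongly successive pH steps depend on one
another: white (flat spectrum) means no dependency, while pink, brown and
black indicate increasingly steep 1/f^|slope| spectra, i.e. increasingly
persistent community structure along the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .series import PhSeries

__all__ = [
    "periodogram_slope",
    "classify_noise",
    "noise_profile",
    "NeutralityResult",
    "neutrality_test",
]

NOISE_TYPES = ("black", "brown", "pink", "white", "none")

#: left-closed slope bins, centred on the canonical exponents 0/-1/-2/-3
PINK_MAX = -0.5
BROWN_MAX = -1.5
BLACK_MAX = -2.5
SLOPE_ALPHA = 0.05


def periodogram_slope(x: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of log power on log frequency.

    The series is mean-detrended, its one-sided periodogram taken over the
    positive frequencies, and the spectral exponent estimated by OLS of
    log10(power) on log10(frequency).  Returns ``(slope, p)`` with ``p`` the
    two-sided significance of the slope.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError("periodogram_slope needs at least 32 steps")
    if np.ptp(x) == 0:
        raise ValueError("degenerate spectrum: constant series")
    freqs, power = signal.periodogram(x, detrend="constant")
    freqs, power = freqs[1:], power[1:]
    ok = power > 0
    if ok.sum() < 4:
        raise ValueError("degenerate spectrum: too few positive periodogram "
                         "ordinates")
    fit = stats.linregress(np.log10(freqs[ok]), np.log10(power[ok]))
    return float(fit.slope), float(fit.pvalue)


def classify_noise(slope: float, pvalue: float) -> str:
    """Map a spectral slope and its significance to a noise color.

    White when the slope is not significantly negative (p >= 0.05) or is
    shallower than -0.5; otherwise pink on [-1.5, -0.5), brown on
    [-2.5, -1.5) and black below -2.5 (left-closed bins).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if pvalue >= SLOPE_ALPHA or slope >= PINK_MAX:
        return "white"
    if slope >= BROWN_MAX:
        return "pink"
    if slope >= BLACK_MAX:
        return "brown"
    return "black"


def noise_profile(series: PhSeries, exclude_interpolated: bool = True) -> pd.DataFrame:
    """Classify the noise color of every taxon in a pH series.

    Interpolated steps are dropped by default — linear interpolation
    manufactures autocorrelation that would redden the spectrum.  Taxa whose
    (retained) series is degenerate get type ``none``.
    """
    keep = ~series.interpolated if exclude_interpolated else np.ones(
        series.n_steps, dtype=bool)
    rows = []
    for k, taxon in enumerate(series.taxa):
        x = series.values[k, keep]
        try:
            slope, p = periodogram_slope(x)
            rows.append((taxon, slope, p, classify_noise(slope, p)))
        except ValueError:
            rows.append((taxon, np.nan, np.nan, "none"))
    return pd.DataFrame(rows, columns=["taxon", "slope", "pvalue", "noise_type"]
                        ).set_index("taxon")


def noise_fractions(profile: pd.DataFrame) -> pd.Series:
    """Fraction of classified taxa per noise color (sums to 1)."""
    classified = profile.loc[profile["noise_type"] != "none", "noise_type"]
    if classified.empty:
        return pd.Series(dtype=float)
    return classified.value_counts(normalize=True)


@dataclass
class NeutralityResult:
    statistic: float
    pvalue: float
    verdict: str          # "neutral" | "structured"
    threshold: float
    n_perm: int


def _predictability(values: np.ndarray, ridge: float = 1e-6,
                    n_folds: int = 4) -> float:
    """Mean cross-validated R^2 of one-step increments predicted linearly
    from the community state (contiguous-block folds)."""
    n_taxa, n_steps = values.shape
    X = values[:, :-1].T                      # state at t
    Xc = np.column_stack([np.ones(len(X)), X])
    pen = np.eye(Xc.shape[1]) * ridge
    pen[0, 0] = 0.0
    bounds = np.linspace(0, len(X), n_folds + 1).astype(int)
    folds = []
    for k in range(n_folds):
        te = np.arange(bounds[k], bounds[k + 1])
        tr = np.concatenate([np.arange(0, bounds[k]),
                             np.arange(bounds[k + 1], len(X))])
        folds.append((tr, te))
    scores = []
    for i in range(n_taxa):
        y = np.diff(values[i])
        r2s = []
        for tr, te in folds:
            Xtr, ytr = Xc[tr], y[tr]
            beta = np.linalg.solve(Xtr.T @ Xtr + pen, Xtr.T @ ytr)
            resid = y[te] - Xc[te] @ beta
            denom = np.sum((y[te] - y[te].mean()) ** 2)
            if denom <= 0:
                continue
            r2s.append(1.0 - np.sum(resid ** 2) / denom)
        if r2s:
            scores.append(np.mean(r2s))
    if not scores:
        raise ValueError("degenerate series: no predictable taxa")
    return float(np.mean(scores))


def neutrality_test(
    series: PhSeries | np.ndarray,
    threshold: float = 0.5,
    n_perm: int = 500,
    seed: int | None = 0,
) -> NeutralityResult:
    """Screen the series for temporal structure before interaction inference.

    The statistic is the mean cross-validated R^2 of a linear one-step
    predictor of each taxon's increment from the full community state.  The
    null distribution comes from cyclically shifting every taxon's series by
    an independent random offset, which destroys cross-taxon alignment while
    preserving each taxon's marginal autocorrelation.  The verdict is
    ``structured`` iff p <= threshold (the screen deliberately uses a lax
    threshold so that only clearly structure-free series are set aside).
    """
    values = series.values if isinstance(series, PhSeries) else np.asarray(
        series, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("neutrality_test needs at least 2 taxa")
    if values.shape[1] < 32:
        raise ValueError("neutrality_test needs at least 32 steps")
    rng = np.random.default_rng(seed)
    observed = _predictability(values)
    n_steps = values.shape[1]
    count = 0
    for _ in range(n_perm):
        shifts = rng.integers(1, n_steps, size=values.shape[0])
        null = np.vstack([np.roll(values[i], s)
                          for i, s in enumerate(shifts)])
        if _predictability(null) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    verdict = "structured" if p <= threshold else "neutral"
    return NeutralityResult(observed, float(p), verdict, threshold, n_perm)
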