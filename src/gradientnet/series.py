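"""Construction of an equally spaced pH pseudo-series from pH-annotated
samples, the object that time-series machinery (spectral diagnostics,
Ricker-model inference) operates on."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PhSeries", "build_ph_series"]


def _step_index(ph: float, step: float) -> int:
    # round-half-up to the nearest grid step; avoids banker's rounding
    return int(np.floor(ph / step + 0.5))


@dataclass
class PhSeries:
    """Taxa x equally-spaced-pH-steps matrix of relative abundances.

    ``values[i, t]`` is the proportion of taxon i at pH ``start_ph + t*step``.
    ``interpolated[t]`` flags steps filled by linear interpolation rather
    than observed samples; ``provenance`` maps each observed step index to
    the contributing sample ids.
    """

    taxa: list[str]
    start_ph: float
    step: float
    values: np.ndarray
    interpolated: np.ndarray
    provenance: dict[int, list[str]] = field(default_factory=dict)

    @property
    def ph_grid(self) -> np.ndarray:
        return self.start_ph + self.step * np.arange(self.values.shape[1])

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{p:.2f}" for p in self.ph_grid]
        return pd.DataFrame(self.values, index=self.taxa, columns=cols)

    def subset(self, taxa: list[str]) -> "PhSeries":
        """Row-subset to ``taxa`` without renormalising the proportions."""
        pos = {t: k for k, t in enumerate(self.taxa)}
        idx = [pos[t] for t in taxa]
        return PhSeries(list(taxa), self.start_ph, self.step,
                        self.values[idx].copy(), self.interpolated.copy(),
                        dict(self.provenance))


def build_ph_series(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    ph_max: float = 5.1,
    step: float = 0.01,
    max_gap: int = 10,
) -> PhSeries:
    """Build the acidic-range pH pseudo-series from a count table.

    Samples with pH < ``ph_max`` are rounded (half-up) to the nearest
    ``step``-grid point; samples sharing a grid point are averaged after
    per-sample proportion normalisation; interior missing steps are filled by
    linear interpolation between the flanking observed steps and flagged.
    A run of more than ``max_gap`` consecutive missing steps is an error.
    """
    ph = meta.loc[meta.index.intersection(table.index), "pH"]
    acid = ph[ph < ph_max]
    if len(acid) < 3:
        raise ValueError(
            f"insufficient data: only {len(acid)} samples with pH < {ph_max}")
    sub = table.loc[acid.index].to_numpy(dtype=float)
    totals = sub.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = acid.index[(totals <= 0).ravel()]
        raise ValueError(f"all-zero samples in series range: {list(bad)}")
    props = sub / totals

    steps_idx = np.array([_step_index(p, step) for p in acid.to_numpy()])
    k0, k1 = int(steps_idx.min()), int(steps_idx.max())
    n_steps = k1 - k0 + 1
    n_taxa = table.shape[1]

    values = np.full((n_taxa, n_steps), np.nan)
    provenance: dict[int, list[str]] = {}
    for k in np.unique(steps_idx):
        members = steps_idx == k
        values[:, k - k0] = props[members].mean(axis=0)
        provenance[int(k - k0)] = list(acid.index[members])

    observed = ~np.isnan(values[0])
    interpolated = ~observed

    # check gap sizes before filling
    run = 0
    for t in range(n_steps):
        if observed[t]:
            run = 0
            continue
        run += 1
        if run > max_gap:
            lo_ph = (k0 + t - run + 1) * step
            hi_ph = (k0 + t) * step
            raise ValueError(
                f"gap of more than {max_gap} steps in the pH series "
                f"(missing at least {lo_ph:.2f}-{hi_ph:.2f})")

    obs_t = np.flatnonzero(observed)
    for i in range(n_taxa):
        values[i] = np.interp(np.arange(n_steps), obs_t, values[i, obs_t])

    if interpolated.any():
        logger.info("build_ph_series: interpolated %d of %d steps",
                    int(interpolated.sum()), n_steps)
    return PhSeries(
        taxa=list(table.columns),
        start_ph=k0 * step,
        step=step,
        values=values,
        interpolated=interpolated,
        provenance=provenance,
    )
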