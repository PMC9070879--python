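"""Posterior summarization primitives.

MAP point estimates (kernel-density mode), highest density intervals,
directional probabilities and MCMC convergence diagnostics, shared by
the reliability and strength-endurance modules.  Summaries follow the
Kruschke-style convention: a posterior is reported as its Maximum a
Posteriori estimate with a 90 % highest density interval, and an
effect direction supported by >= 90 % of posterior mass is "clear".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLEAR_THRESHOLD",
    "MIN_DRAWS",
    "DrawVector",
    "PosteriorSummary",
    "hdi",
    "map_estimate",
    "prob_direction",
    "summarize",
    "convergence_report",
]

#: posterior probability of one direction required to call an effect "clear"
CLEAR_THRESHOLD = 0.90
#: minimum number of draws accepted by any summarization call
MIN_DRAWS = 100

_KDE_GRID = 512  # grid resolution for locating the KDE mode


@dataclass(frozen=True)
class DrawVector:
    """Posterior draws of one scalar quantity, with optional chain labels."""

    values: np.ndarray
    name: str = ""
    chain: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PosteriorSummary:
    map: float
    hdi_low: float
    hdi_high: float
    prob_direction: float
    clear: bool

    def as_dict(self) -> dict:
        return {
            "map": self.map,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "prob_direction": self.prob_direction,
            "clear": self.clear,
        }


def _values(draws) -> np.ndarray:
    v = draws.values if isinstance(draws, DrawVector) else np.asarray(draws, dtype=float)
    v = v.ravel()
    if v.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("draws contain non-finite values")
    return v


def hdi(draws, mass: float = 0.90) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Computed by sliding a window of ``ceil(mass * n)`` consecutive
    sorted draws and keeping the narrowest; assumes a unimodal
    posterior, which holds for every quantity this package reports.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    v = np.sort(_values(draws))
    n = v.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(v[0]), float(v[-1])
    widths = v[k:] - v[: n - k]
    i = int(np.argmin(widths))
    return float(v[i]), float(v[i + k])


def map_estimate(draws) -> float:
    """Posterior mode from a Gaussian KDE, located by two-stage grid search.

    The bandwidth is a skew-adapted robust Silverman rule:
    ``0.9 * min(sd, IQR/1.34) * n**(-1/5) * 3 / (1 + 2*|skew|)``.
    Mode location tolerates more smoothing than density estimation when
    the posterior is symmetric (smoothing adds no bias, only reduces
    argmax noise) but needs much less when it is skewed (Silverman's
    rule drags the mode toward the long tail); the skew factor trades
    the two off.  A second 512-point grid pass refines the coarse
    winner so heavy tails cannot starve the peak of grid resolution.
    """
    v = _values(draws)
    lo, hi = float(v.min()), float(v.max())
    sd = float(np.std(v, ddof=1))
    if lo == hi or sd == 0.0:
        return lo
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    skew = abs(float(stats.skew(v)))
    h = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * v.size ** (-0.2) * 3.0 / (1.0 + 2.0 * skew)
    kde = stats.gaussian_kde(v, bw_method=h / sd)
    # heavy-tailed draw vectors (e.g. ratios with near-zero denominators)
    # would starve the peak of grid resolution: search the dense region only
    q_lo, q_hi = np.percentile(v, [0.5, 99.5])
    if (q_hi - q_lo) > 0:
        lo, hi = float(q_lo), float(q_hi)
    grid = np.linspace(lo, hi, _KDE_GRID)
    dens = kde(grid)
    spacing = grid[1] - grid[0]
    if not np.all(np.isfinite(dens)) or h < 0.5 * spacing or float(dens.sum() * spacing) < 0.5:
        # bandwidth collapsed below the grid resolution (a near-degenerate
        # spike with distant outliers): locate the modal cell by histogram
        counts, edges = np.histogram(v, bins=_KDE_GRID, range=(lo, hi))
        b = int(np.argmax(counts))
        in_cell = v[(v >= edges[b]) & (v <= edges[b + 1])]
        return float(np.median(in_cell))
    best = int(np.argmax(dens))
    fine = np.linspace(max(grid[best] - spacing, lo), min(grid[best] + spacing, hi), _KDE_GRID)
    return float(fine[np.argmax(kde(fine))])


def prob_direction(draws) -> float:
    """max(P(x > 0), P(x < 0)) over the draws; >= 0.90 counts as a clear direction."""
    v = _values(draws)
    p_pos = float(np.mean(v > 0))
    p_neg = float(np.mean(v < 0))
    return max(p_pos, p_neg)


def summarize(draws, mass: float = 0.90) -> PosteriorSummary:
    lo, hi = hdi(draws, mass)
    pd_ = prob_direction(draws)
    return PosteriorSummary(map_estimate(draws), lo, hi, pd_, pd_ >= CLEAR_THRESHOLD)


# ---------------------------------------------------------------------------
# convergence diagnostics

RHAT_MAX = 1.01
ESS_MIN = 400


def convergence_report(chain_draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Split R-hat and effective sample size per quantity.

    ``chain_draws`` maps a quantity name to a (chain, draw) array with
    at least two chains.  The returned frame has columns ``rhat``,
    ``ess_bulk`` and ``ok`` plus an ``attrs['usable']`` flag that is
    False when any R-hat exceeds 1.01 or any ESS falls below 400.
    """
    import arviz as az

    rows = {}
    for name, arr in chain_draws.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"{name}: need draws from >= 2 chains, got shape {arr.shape}")
        ds = az.convert_to_dataset(arr)  # interpreted as (chain, draw)
        rhat = float(az.rhat(ds)["x"].values)
        ess = float(az.ess(ds, method="bulk")["x"].values)
        rows[name] = {"rhat": rhat, "ess_bulk": ess, "ok": (rhat <= RHAT_MAX) and (ess >= ESS_MIN)}
    report = pd.DataFrame(rows).T
    report.attrs["usable"] = bool(report["ok"].all())
    return report
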