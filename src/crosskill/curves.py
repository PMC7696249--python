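"""Dose-response fitting, serial dilutions, Bliss synergy, doubling times.

The dose-response model is the four-parameter logistic (4PL)

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

with ic50 the inflection (relative EC50).  The absolute 50%-viability
crossing is reported alongside when it exists.  Synergy uses Bliss
independence: with single-agent inhibition fractions Ea and Eb the expected
combination inhibition is Ea + Eb - Ea*Eb, and positive excess
(observed - expected) indicates synergy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import four_pl

__all__ = ["dilution_series", "fit_4pl", "bliss_excess", "doubling_time",
           "DoseResponseFit", "CombinationGrid", "DoublingTime"]


def dilution_series(start, fold, n_points):
    """Serial dilution concentrations: start / fold**i, i = 0..n_points-1."""
    if start <= 0:
        raise ValueError("start concentration must be positive")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return start / np.power(float(fold), np.arange(n_points))


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    ic50_in_range: bool
    absolute_ic50: float   # concentration where fitted viability = 50%; NaN if never crossed
    n_points: int

    def predict(self, c):
        return four_pl(c, self.top, self.bottom, self.ic50, self.hill)

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("top", "bottom", "ic50", "hill", "rss", "converged",
                 "ic50_in_range", "absolute_ic50", "n_points")}


def _absolute_ic50(top, bottom, ic50, hill, level=50.0):
    lo, hi = min(top, bottom), max(top, bottom)
    if not (lo < level < hi) or hill == 0:
        return float("nan")
    x = (top - level) / (level - bottom)
    return float(ic50 * x ** (1.0 / hill))


def fit_4pl(concentrations, viabilities, max_starts=12):
    """Least-squares 4PL fit with multi-start initialization.

    Replicate observations are allowed (pass repeated concentrations).  The
    fit is canonicalized to top >= bottom via the 4PL symmetry
    (top, bottom, hill) -> (bottom, top, -hill); ``ic50_in_range`` is False
    when the fitted ic50 falls outside the tested concentrations, and
    ``converged`` is False (with best-effort parameters) when no start
    converges or the response carries no dose information.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if c.shape != v.shape:
        raise ValueError("concentrations and viabilities must align")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    top0, bot0 = float(v.max()), float(v.min())
    ic50_grid = np.geomspace(c.min(), c.max(), 4)
    hill_grid = (1.0, 2.0, 0.5, -1.0)
    starts = [(top0, bot0, ic, h) for h in hill_grid for ic in ic50_grid][:max_starts]

    best, best_rss = None, np.inf
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                four_pl, c, v, p0=p0,
                bounds=([-np.inf, -np.inf, 1e-12, -50.0], [np.inf, np.inf, 1e12, 50.0]),
                maxfev=20000, xtol=1e-14, ftol=1e-14)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rss = float(np.sum((four_pl(c, *popt) - v) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss

    if best is None:
        # flat/degenerate response: report the mean as a flat curve
        mean = float(v.mean())
        return DoseResponseFit(mean, mean, float(np.sqrt(c.min() * c.max())), 1.0,
                               float(np.sum((v - mean) ** 2)), False, False,
                               float("nan"), len(c))
    top, bottom, ic50, hill = (float(x) for x in best)
    if bottom > top:  # canonical form: top >= bottom, hill sign flips
        top, bottom, hill = bottom, top, -hill
    span = abs(top - bottom)
    noise_scale = max(np.std(v), 1e-12)
    converged = span > 1e-3 * max(noise_scale, 1.0)
    in_range = bool(c.min() <= ic50 <= c.max())
    return DoseResponseFit(top, bottom, ic50, hill, best_rss, bool(converged),
                           in_range, _absolute_ic50(top, bottom, ic50, hill), len(c))


@dataclass
class CombinationGrid:
    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: pd.DataFrame    # interior cells, index doses_a, columns doses_b
    expected: pd.DataFrame    # Bliss expectation from single-agent rows/columns
    excess: pd.DataFrame      # observed - expected
    effect_a: pd.Series       # single-agent inhibition of A per dose
    effect_b: pd.Series
    summary_excess: float     # mean excess over interior cells

    def to_dict(self):
        return {"summary_excess": self.summary_excess,
                "doses_a": list(map(float, self.doses_a)),
                "doses_b": list(map(float, self.doses_b))}


def bliss_excess(grid):
    """Bliss-excess surface for a checkerboard inhibition grid.

    ``grid`` is a DataFrame of observed inhibition fractions indexed by dose
    of drug A (rows) and dose of drug B (columns), each including a zero dose
    whose row/column holds the single-agent effects.  Inhibitions outside
    [0, 1] are clipped with a warning.
    """
    grid = pd.DataFrame(grid).astype(float)
    if 0.0 not in grid.index or 0.0 not in grid.columns:
        raise ValueError("grid must include a zero-dose row and column (single agents)")
    vals = grid.to_numpy()
    if np.any((vals < 0) | (vals > 1)):
        warnings.warn("inhibition values outside [0, 1] clipped")
        grid = grid.clip(0.0, 1.0)
    grid = grid.sort_index().sort_index(axis=1)
    ea = grid.loc[grid.index != 0.0, 0.0]
    eb = grid.loc[0.0, grid.columns != 0.0]
    interior = grid.loc[grid.index != 0.0, grid.columns != 0.0]
    expected = pd.DataFrame(
        ea.to_numpy()[:, None] + eb.to_numpy()[None, :]
        - ea.to_numpy()[:, None] * eb.to_numpy()[None, :],
        index=interior.index, columns=interior.columns)
    excess = interior - expected
    return CombinationGrid(interior.index.to_numpy(float), interior.columns.to_numpy(float),
                           interior, expected, excess, ea, eb,
                           float(excess.to_numpy().mean()))


@dataclass
class DoublingTime:
    doubling_time_h: float     # inf when flat; negative (halving time sign) when declining
    growth_rate_per_h: float
    r_squared: float
    flag: str                  # '', 'flat', 'declining'

    def __float__(self):
        return self.doubling_time_h


def doubling_time(times_h, abundances):
    """Doubling time from log-linear regression of abundance on time.

    Td = ln 2 / slope of ln(abundance) vs time.  A zero slope yields inf with
    flag 'flat'; a negative slope yields the signed (negative) value with
    flag 'declining' rather than a silent positive number.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(a <= 0):
        raise ValueError("abundances must be positive")
    slope, intercept = np.polyfit(t, np.log(a), 1)
    resid = np.log(a) - (slope * t + intercept)
    ss_tot = np.sum((np.log(a) - np.log(a).mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    if abs(slope) < 1e-14:  # numerically flat
        return DoublingTime(float("inf"), 0.0, r2, "flat")
    td = float(np.log(2.0) / slope)
    return DoublingTime(td, float(slope), r2, "declining" if slope < 0 else "")
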