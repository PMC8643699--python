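"""Height-growth curve smoothing and flowering-phenology classification.

Weekly plant heights are smoothed with a cubic smoothing spline whose
smoothing level is chosen to hit a target effective degrees of freedom
(default 7 for ~10-12 weekly points, reproducing a lightly smoothed
``spar=0.35``-style fit); the
maximum growth rate and its day are read off the spline derivative on a
50-point grid, optionally restricted to the log-linear part of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "fit_growth",
    "flowering_class",
    "segregation_counts",
]


@dataclass(frozen=True)
class GrowthSeries:
    """One plant's height time series: days after planting and heights (cm)."""

    days: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "heights", heights)
        if days.shape != heights.shape or days.ndim != 1:
            raise ValueError("days and heights must be 1-D and equal length")
        if not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(heights < 0):
            raise ValueError("heights must be non-negative")


@dataclass
class GrowthFit:
    """Smoothed growth curve and its rate statistics."""

    smoothed: object            # callable day -> height
    derivative: object          # callable day -> cm/day
    max_rate: float             # cm d⁻¹
    day_of_max: float           # DAP
    mean_rate: float            # (last − first height) / elapsed days
    edf: float | None = None    # effective degrees of freedom actually used


def _edf(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Trace of the smoothing-spline hat matrix (the fit is linear in y)."""
    n = x.size
    tr = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        tr += make_smoothing_spline(x, e, lam=lam)(x[i])
    return tr


def _spline_for_edf(x, y, target_edf: float):
    """Bisection on log-lambda so the spline's effective df ≈ target."""
    lo, hi = -12.0, 12.0
    # edf decreases with lambda; widen until bracketed
    f = lambda loglam: _edf(x, y, 10.0 ** loglam) - target_edf
    flo, fhi = f(lo), f(hi)
    if flo < 0:      # even the roughest fit is smoother than requested
        return make_smoothing_spline(x, y, lam=10.0 ** lo)
    if fhi > 0:
        return make_smoothing_spline(x, y, lam=10.0 ** hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return make_smoothing_spline(x, y, lam=10.0 ** (0.5 * (lo + hi)))


def _loglinear_window(days: np.ndarray, heights: np.ndarray,
                      r2_min: float = 0.95) -> tuple[float, float]:
    """Interval where log-height is locally linear: the span of observation
    triplets whose 3-point log-linear fit has R² above ``r2_min``."""
    h = np.maximum(heights, 1e-9)
    logh = np.log(h)
    good: list[int] = []
    for i in range(len(days) - 2):
        d = days[i:i + 3]
        z = logh[i:i + 3]
        r = np.corrcoef(d, z)[0, 1]
        if np.isfinite(r) and r * r > r2_min:
            good.extend(range(i, i + 3))
    if not good:
        return float(days[0]), float(days[-1])
    return float(days[min(good)]), float(days[max(good)])


def fit_growth(series: GrowthSeries, target_edf: float = 7.0,
               grid_points: int = 50,
               restrict_loglinear: bool = True) -> GrowthFit:
    """Fit the smoothing spline and extract growth-rate statistics.

    With fewer than 4 points, falls back to piecewise-linear interpolation
    (with a warning); ``max_rate`` is then the largest segment slope.
    """
    days, heights = series.days, series.heights
    mean_rate = float((heights[-1] - heights[0]) / (days[-1] - days[0]))

    if days.size < 4:
        warnings.warn("fewer than 4 points: piecewise-linear fallback",
                      stacklevel=2)
        slopes = np.diff(heights) / np.diff(days)
        j = int(np.argmax(slopes))
        interp = lambda d: np.interp(d, days, heights)
        deriv = lambda d: np.interp(
            d, 0.5 * (days[:-1] + days[1:]), slopes)
        return GrowthFit(interp, deriv, float(slopes[j]),
                         float(0.5 * (days[j] + days[j + 1])), mean_rate)

    target_edf = min(target_edf, days.size - 0.5)
    spl = _spline_for_edf(days, heights, target_edf)
    dspl = spl.derivative()

    lo, hi = days[0], days[-1]
    if restrict_loglinear and np.all(heights > 0):
        lo, hi = _loglinear_window(days, heights)
    grid = np.linspace(lo, hi, grid_points)
    rates = dspl(grid)
    j = int(np.argmax(rates))
    return GrowthFit(spl, dspl, float(rates[j]), float(grid[j]), mean_rate,
                     edf=target_edf)


def flowering_class(pre_terminal_day: float) -> str:
    """Classify flowering phenology by pre-terminal flowering day:
    early (<50 DAP), mid (50–70 DAP inclusive), late (>70 DAP)."""
    if pre_terminal_day < 0:
        raise ValueError("flowering day must be non-negative")
    if pre_terminal_day < 50:
        return "early"
    if pre_terminal_day <= 70:
        return "mid"
    return "late"


_RATIOS = {          # early : not-early candidate segregation patterns
    "all-early": (1, 0),
    "all-late": (0, 1),
    "1:1": (1, 1),
    "2:1": (2, 1),
    "1:2": (1, 2),
    "3:1": (3, 1),
    "1:3": (1, 3),
}


def segregation_counts(classes: dict[str, list[str]]) -> dict[str, dict]:
    """Per-family early/mid/late counts and the closest simple segregation
    ratio of early vs later flowering (reported, not tested).

    Parameters
    ----------
    classes : mapping of family id -> list of class labels per plant.

    The closest pattern among all-early, all-late, 1:1, 2:1 (either
    direction) and 3:1 (either direction) is chosen by chi-square distance
    on (early, mid+late) counts.
    """
    out = {}
    for fam, labels in classes.items():
        if len(labels) == 0:
            raise ValueError(f"family {fam} has no plants")
        n_e = sum(1 for c in labels if c == "early")
        n_m = sum(1 for c in labels if c == "mid")
        n_l = sum(1 for c in labels if c == "late")
        n = len(labels)
        obs = np.array([n_e, n_m + n_l], dtype=float)
        best, best_d = None, np.inf
        for name, (p, q) in _RATIOS.items():
            exp = n * np.array([p, q], dtype=float) / (p + q)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.where(exp > 0, (obs - exp) ** 2 / exp, np.inf)
            # zero-expectation cells only match zero observations
            d = np.where((exp == 0) & (obs == 0), 0.0, d)
            dist = float(d.sum())
            if dist < best_d:
                best, best_d = name, dist
        out[fam] = {"early": n_e, "mid": n_m, "late": n_l,
                    "closest_ratio": best, "chi_square": best_d}
    return out
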