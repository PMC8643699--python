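"""Model-II (errors-in-both-variables) bivariate regression.

Implements ordinary least squares (OLS), major axis (MA), standardized major
axis (SMA, also called reduced major axis), and ranged major axis (RMA)
slopes, the last being the estimator used throughout the allometric scaling
analyses here.  RMA standardizes both variables by their observed ranges,
fits the major axis in standardized space, and back-transforms the slope;
the intercept always passes through the centroid.

The log–log convenience constructor fits the same estimators to
log10-transformed data, so the slope is the allometric scaling exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["Model2Regression", "Model2Results", "fit_loglog", "model2_regress"]

_METHODS = ("OLS", "MA", "SMA", "RMA")


@dataclass
class Model2Results:
    """Fitted slope/intercept of a bivariate model-II regression.

    Attributes
    ----------
    method : one of ``OLS``, ``MA``, ``SMA``, ``RMA``.
    slope, intercept : fitted line (intercept through the centroid for the
        model-II methods).
    r_squared : squared Pearson correlation of the two variables.
    slope_ci : 95% confidence interval on the slope.
    n : number of observations.
    log10 : True when the fit was done on log10-transformed data.
    """

    method: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_ci: tuple[float, float]
    log10: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.log10:
            return 10.0 ** (self.intercept + self.slope * np.log10(x))
        return self.intercept + self.slope * x

    def summary(self) -> str:
        scale = "log10–log10" if self.log10 else "linear"
        lo, hi = self.slope_ci
        return (
            f"Model-II regression ({self.method}, {scale})\n"
            f"  n          {self.n}\n"
            f"  slope      {self.slope:.4f}  (95% CI {lo:.4f}, {hi:.4f})\n"
            f"  intercept  {self.intercept:.4f}\n"
            f"  R^2        {self.r_squared:.4f}"
        )


class Model2Regression:
    """Bivariate regression treating both variables as error-prone.

    Parameters
    ----------
    x, y : 1-D arrays of equal length, n >= 3, finite.
    log10 : fit on log10(x), log10(y); requires strictly positive data.

    Examples
    --------
    >>> res = Model2Regression([1, 2, 3], [3, 5, 7]).fit("SMA")
    >>> round(res.slope, 6)
    2.0
    """

    def __init__(self, x, y, log10: bool = False):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if x.size < 3:
            raise ValueError(f"need n >= 3 observations, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("x and y must be finite")
        if log10:
            bad = np.nonzero((x <= 0) | (y <= 0))[0]
            if bad.size:
                raise ValueError(
                    f"log–log fit requires positive values; offending indices: "
                    f"{bad.tolist()}"
                )
            x, y = np.log10(x), np.log10(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("zero variance in x or y")
        self.x = x
        self.y = y
        self.log10 = log10

    # -- slope estimators ---------------------------------------------------
    @staticmethod
    def _ma_slope(x: np.ndarray, y: np.ndarray) -> float:
        """Major-axis slope: first principal axis of the covariance matrix."""
        sxx = np.var(x, ddof=1)
        syy = np.var(y, ddof=1)
        sxy = np.cov(x, y, ddof=1)[0, 1]
        if sxy == 0:
            # Axis-aligned covariance: MA is the dominant-variance axis.
            return 0.0 if sxx >= syy else math.inf
        d = syy - sxx
        return (d + math.sqrt(d * d + 4.0 * sxy * sxy)) / (2.0 * sxy)

    def _slope(self, method: str) -> float:
        x, y = self.x, self.y
        r = np.corrcoef(x, y)[0, 1]
        if method == "OLS":
            return np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        if method == "MA":
            return self._ma_slope(x, y)
        if method == "SMA":
            return math.copysign(np.std(y, ddof=1) / np.std(x, ddof=1), r)
        if method == "RMA":
            # Range-standardize both axes, fit MA, back-transform the slope.
            rx, ry = np.ptp(x), np.ptp(y)
            xs = (x - x.min()) / rx
            ys = (y - y.min()) / ry
            return self._ma_slope(xs, ys) * ry / rx
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")

    def _slope_ci(self, method: str, slope: float) -> tuple[float, float]:
        """95% CI on the slope.

        OLS: the usual t-based interval.  SMA/RMA: Pitman/Legendre interval
        from the correlation; MA: the same interval applied to the MA slope
        (a serviceable large-sample approximation).
        """
        x, y, n = self.x, self.y, self.x.size
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        if n <= 2:
            return (-math.inf, math.inf)
        if method == "OLS":
            res = stats.linregress(x, y)
            t = stats.t.ppf(0.975, n - 2)
            return (slope - t * res.stderr, slope + t * res.stderr)
        f = stats.f.ppf(0.95, 1, n - 2)
        B = f * (1.0 - r2) / (n - 2)
        lo = slope * (math.sqrt(B + 1.0) - math.sqrt(B))
        hi = slope * (math.sqrt(B + 1.0) + math.sqrt(B))
        return (min(lo, hi), max(lo, hi))

    def fit(self, method: str = "RMA") -> Model2Results:
        method = method.upper()
        slope = self._slope(method)
        xbar, ybar = self.x.mean(), self.y.mean()
        intercept = ybar - slope * xbar
        r2 = float(np.corrcoef(self.x, self.y)[0, 1] ** 2)
        return Model2Results(
            method=method,
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
            n=int(self.x.size),
            slope_ci=self._slope_ci(method, slope),
            log10=self.log10,
        )


def model2_regress(x, y, method: str = "RMA") -> Model2Results:
    """Functional form of :class:`Model2Regression` on the raw scale."""
    return Model2Regression(x, y).fit(method)


def fit_loglog(x, y, method: str = "RMA") -> Model2Results:
    """Allometric scaling fit: model-II regression of log10(y) on log10(x).

    The returned slope is the scaling exponent; the intercept is the base-10
    log of the allometric coefficient.
    """
    return Model2Regression(x, y, log10=True).fit(method)
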