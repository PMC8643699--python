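"""Predictor selection and relative-importance decomposition for yield models.

``stepwise_aic`` performs bidirectional stepwise OLS selection on
AIC = n·log(RSS/n) + 2(k+1) starting from the full model.  ``LMGImportance``
decomposes the full-model R² into nonnegative per-predictor LMG shares —
the average, over all orderings of the predictors, of the increase in R²
when each predictor enters — with bootstrap confidence intervals at a
Bonferroni-adjusted level.  The shares sum exactly to the model R²
irrespective of predictor correlation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["stepwise_aic", "StepwiseResult", "LMGImportance", "ImportanceDecomposition"]


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of OLS of y on [1, X]."""
    A = np.column_stack([np.ones(y.size), X]) if X.size else np.ones((y.size, 1))
    _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def _aic(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    k = X.shape[1] if X.ndim == 2 else 0
    rss = max(_rss(y, X), 1e-300)
    return n * math.log(rss / n) + 2.0 * (k + 1)


@dataclass
class StepwiseResult:
    selected: list[str]
    aic: float
    r_squared: float
    coefficients: pd.Series
    history: list[tuple[str, str, float]]   # (step, predictor, aic)


def stepwise_aic(y, X: pd.DataFrame) -> StepwiseResult:
    """Bidirectional stepwise OLS selection by AIC, starting from the full
    model.  Ties are broken by predictor (column) order, so the search is
    deterministic.  Aliased (collinear-singular) columns are dropped first
    with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = pd.DataFrame(X).astype(float)
    n, p = y.size, X.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")

    # drop aliased columns: greedily keep columns that increase design rank
    kept: list[str] = []
    for c in X.columns:
        trial = np.column_stack([np.ones(n)] + [X[k].to_numpy() for k in kept + [c]])
        if np.linalg.matrix_rank(trial) == len(kept) + 2:
            kept.append(c)
        else:
            warnings.warn(f"dropping aliased predictor {c!r}", stacklevel=2)
    X = X[kept]

    current = list(X.columns)
    cur_aic = _aic(y, X[current].to_numpy())
    history = [("start", "+".join(current) or "(intercept)", cur_aic)]
    improved = True
    while improved:
        improved = False
        best = (cur_aic, None, None)
        for c in current:                                  # backward steps
            cand = [k for k in current if k != c]
            a = _aic(y, X[cand].to_numpy() if cand else np.empty((n, 0)))
            if a < best[0] - 1e-12:
                best = (a, "drop", c)
        for c in X.columns:                                # forward steps
            if c in current:
                continue
            a = _aic(y, X[current + [c]].to_numpy())
            if a < best[0] - 1e-12:
                best = (a, "add", c)
        if best[1] is not None:
            cur_aic = best[0]
            if best[1] == "drop":
                current.remove(best[2])
            else:
                current.append(best[2])
            history.append((best[1], best[2], cur_aic))
            improved = True

    current = [c for c in X.columns if c in current]       # canonical order
    Xs = X[current].to_numpy() if current else np.empty((n, 0))
    A = np.column_stack([np.ones(n), Xs]) if current else np.ones((n, 1))
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - _rss(y, Xs) / tss if tss > 0 else 0.0
    return StepwiseResult(
        selected=current,
        aic=cur_aic,
        r_squared=r2,
        coefficients=pd.Series(beta, index=["const"] + current),
        history=history,
    )


@dataclass
class ImportanceDecomposition:
    """LMG shares of R² per predictor, with bootstrap CIs."""

    predictors: list[str]
    shares: pd.Series              # LMG share of R² per predictor
    r_squared: float               # full-model R² (= sum of shares)
    ci: pd.DataFrame | None = None       # columns: lower, upper
    ci_level: float | None = None        # Bonferroni-adjusted per-predictor level
    n_boot: int = 0

    def summary(self) -> str:
        lines = [f"LMG decomposition of R² = {self.r_squared:.4f}"]
        for p in self.predictors:
            s = f"  {p:<12s} {self.shares[p]:.4f}"
            if self.ci is not None:
                s += f"  [{self.ci.loc[p, 'lower']:.4f}, {self.ci.loc[p, 'upper']:.4f}]"
            lines.append(s)
        return "\n".join(lines)


def _r2_all_subsets(y: np.ndarray, X: np.ndarray) -> dict[frozenset, float]:
    """R² of the OLS fit for every predictor subset (2^p fits)."""
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    out: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, p + 1):
        for S in itertools.combinations(range(p), r):
            out[frozenset(S)] = 1.0 - _rss(y, X[:, S]) / tss
    return out


def _lmg_shares(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Exact LMG: subset-weighted average of sequential R² gains.

    share_j = Σ_{S ⊆ P\\{j}}  |S|!(p−|S|−1)!/p! · (R²(S∪{j}) − R²(S))
    """
    p = X.shape[1]
    r2 = _r2_all_subsets(y, X)
    fact = [math.factorial(i) for i in range(p + 1)]
    shares = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [i for i in others if i != j]
        for r in range(0, p):
            w = fact[r] * fact[p - r - 1] / fact[p]
            for S in itertools.combinations(rest, r):
                s = frozenset(S)
                shares[j] += w * (r2[s | {j}] - r2[s])
    return shares


def _lmg_shares_sampled(y: np.ndarray, X: np.ndarray, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo LMG over sampled orderings (used when p is large)."""
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    shares = np.zeros(p)
    for _ in range(n_perm):
        order = rng.permutation(p)
        prev = 0.0
        cols: list[int] = []
        for j in order:
            cols.append(j)
            cur = 1.0 - _rss(y, X[:, cols]) / tss
            shares[j] += cur - prev
            prev = cur
    return shares / n_perm


class LMGImportance:
    """LMG relative-importance decomposition of a multiple OLS regression.

    Parameters
    ----------
    y : response vector.
    X : predictor DataFrame (p ≤ 12 for exact enumeration; beyond that,
        orderings are Monte-Carlo sampled).

    ``fit(n_boot=1000, seed=...)`` adds case-resampling bootstrap percentile
    CIs at the Bonferroni-adjusted level 1 − 0.05/p.
    """

    def __init__(self, y, X: pd.DataFrame, n_perm_sample: int = 2000):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = pd.DataFrame(X).astype(float)
        n, p = self.X.shape
        if self.y.size != n:
            raise ValueError("y and X must have the same number of rows")
        if p < 1:
            raise ValueError("need at least one predictor")
        A = np.column_stack([np.ones(n), self.X.to_numpy()])
        if np.linalg.matrix_rank(A) < p + 1:
            raise ValueError("singular design: predictors are collinear")
        self.n_perm_sample = n_perm_sample

    def _shares(self, y, Xv, rng=None) -> np.ndarray:
        p = Xv.shape[1]
        if p <= 12:
            return _lmg_shares(y, Xv)
        rng = rng if rng is not None else np.random.default_rng(0)
        return _lmg_shares_sampled(y, Xv, self.n_perm_sample, rng)

    def fit(self, n_boot: int = 0, seed: int | None = None) -> ImportanceDecomposition:
        Xv = self.X.to_numpy()
        names = list(self.X.columns)
        p = Xv.shape[1]
        rng = np.random.default_rng(seed)
        shares = self._shares(self.y, Xv, rng)
        tss = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - _rss(self.y, Xv) / tss

        ci = None
        level = None
        if n_boot > 0:
            level = 1.0 - 0.05 / p
            alpha = (1.0 - level) / 2.0
            boot = np.empty((n_boot, p))
            n = self.y.size
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                yb, Xb = self.y[idx], Xv[idx]
                if np.linalg.matrix_rank(
                        np.column_stack([np.ones(n), Xb])) < p + 1:
                    boot[b] = shares      # degenerate resample: keep point est
                    continue
                boot[b] = self._shares(yb, Xb, rng)
            lo = np.quantile(boot, alpha, axis=0)
            hi = np.quantile(boot, 1.0 - alpha, axis=0)
            ci = pd.DataFrame({"lower": lo, "upper": hi}, index=names)

        return ImportanceDecomposition(
            predictors=names,
            shares=pd.Series(shares, index=names),
            r_squared=float(r2),
            ci=ci,
            ci_level=level,
            n_boot=n_boot,
        )


def lmg(y, X: pd.DataFrame, n_boot: int = 0, seed: int | None = None
        ) -> ImportanceDecomposition:
    """Functional form of :class:`LMGImportance`."""
    return LMGImportance(y, X).fit(n_boot=n_boot, seed=seed)
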