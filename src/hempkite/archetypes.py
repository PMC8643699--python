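"""Archetypal analysis of canopy form.

Data points are approximated as convex combinations of k "archetypes" that
are themselves convex combinations of the data:  minimize ‖X − A·Z‖² with
Z = B·X and the rows of A (n×k) and B (k×n) on the probability simplex.
Archetypes therefore sit on (or near) the convex hull of the data and
represent extreme canopy forms; each plant gets simplex weights over them.

The canonical use here is two-dimensional: the shape ratios MCD/HT and
MCDH/HT, with k = 4 canopy-form extremes.

Fitting is alternating constrained least squares; each simplex-constrained
subproblem is solved as nonnegative least squares with a sum-to-one
augmentation row.  Restarts are seeded and initialization uses a
furthest-point heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ArchetypalAnalysis",
    "ArchetypeSolution",
    "archetypal_analysis",
    "select_k",
    "assign_archetype",
]

_AUG = 200.0   # weight of the sum-to-one augmentation row


def _simplex_lsq(M: np.ndarray, t: np.ndarray) -> np.ndarray:
    """argmin_a ‖M a − t‖ subject to a ≥ 0, Σa = 1 (augmented NNLS)."""
    k = M.shape[1]
    Ma = np.vstack([M, _AUG * np.ones((1, k))])
    ta = np.append(t, _AUG)
    a, _ = nnls(Ma, ta)
    s = a.sum()
    return a / s if s > 0 else np.full(k, 1.0 / k)


def _weights_for(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Simplex weights of each row of X over the archetypes Z."""
    return np.array([_simplex_lsq(Z.T, x) for x in X])


def _furthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of k spread-out data points: random start, then iteratively
    the point furthest from those already chosen."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(k - 1):
        d = np.min(
            ((X[:, None, :] - X[idx][None, :, :]) ** 2).sum(-1), axis=1
        )
        d[idx] = -1.0
        idx.append(int(np.argmax(d)))
    return np.array(idx)


@dataclass
class ArchetypeSolution:
    """Fitted archetypes and per-point simplex weights."""

    k: int
    Z: np.ndarray          # (k, d) archetype coordinates
    A: np.ndarray          # (n, k) simplex weights
    rss: float
    n_restarts: int
    seed: int | None
    converged: bool
    n_iter: int

    def labels(self) -> np.ndarray:
        """Hard assignment: argmax weight, ties to the lowest index."""
        return np.argmax(self.A, axis=1)


class ArchetypalAnalysis:
    """Archetypal analysis model for a data matrix X (n × d).

    ``fit(k, nrep, seed)`` returns the best :class:`ArchetypeSolution` over
    ``nrep`` seeded restarts; ``extra_inits`` lets a caller supply candidate
    archetype matrices (used by :func:`select_k` to warm-start k+1 from k).
    """

    def __init__(self, X, max_iter: int = 500, tol: float = 1e-8):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        self.X = X
        self.max_iter = max_iter
        self.tol = tol

    def _als(self, Z0: np.ndarray) -> ArchetypeSolution:
        X = self.X
        Z = Z0.copy()
        k = Z.shape[0]
        prev = np.inf
        converged = False
        it = 0
        A = _weights_for(X, Z)
        for it in range(1, self.max_iter + 1):
            # Z-update: unconstrained LS solution projected back onto the
            # data hull through the B simplex weights.
            Zls, *_ = np.linalg.lstsq(A, X, rcond=None)
            B = _weights_for(Zls, X)     # each archetype as convex combo of data
            Z = B @ X
            A = _weights_for(X, Z)
            rss = float(((X - A @ Z) ** 2).sum())
            if math.isfinite(prev) and prev - rss <= self.tol * max(prev, 1e-30):
                converged = True
                prev = min(prev, rss)
                break
            prev = rss
        return ArchetypeSolution(
            k=k, Z=Z, A=A, rss=prev, n_restarts=1, seed=None,
            converged=converged, n_iter=it,
        )

    def fit(self, k: int, nrep: int = 5, seed: int | None = None,
            extra_inits: list[np.ndarray] | None = None) -> ArchetypeSolution:
        n = self.X.shape[0]
        if not 1 <= k < n:
            raise ValueError(f"need 1 <= k < n (k={k}, n={n})")
        rng = np.random.default_rng(seed)
        inits = [self.X[_furthest_point_init(self.X, k, rng)]
                 for _ in range(nrep)]
        for Z0 in extra_inits or []:
            if Z0.shape == (k, self.X.shape[1]):
                inits.append(np.asarray(Z0, dtype=float))
        best = None
        for Z0 in inits:
            sol = self._als(Z0)
            if best is None or sol.rss < best.rss:
                best = sol
        best.n_restarts = len(inits)
        best.seed = seed
        return best

    def transform(self, Xnew, sol: ArchetypeSolution) -> np.ndarray:
        """Simplex weights of new data over a fitted solution's archetypes."""
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.ndim != 2 or Xnew.shape[1] != sol.Z.shape[1]:
            raise ValueError(
                f"dimension mismatch: data has {Xnew.shape[-1]} columns, "
                f"archetypes have {sol.Z.shape[1]}"
            )
        return _weights_for(Xnew, sol.Z)


def archetypal_analysis(X, k: int, nrep: int = 5,
                        seed: int | None = None) -> ArchetypeSolution:
    """Functional form of :class:`ArchetypalAnalysis.fit`."""
    return ArchetypalAnalysis(X).fit(k, nrep=nrep, seed=seed)


def select_k(X, kmax: int = 10, nrep: int = 5, seed: int | None = None) -> dict:
    """Scree of best RSS for k = 1..kmax.

    Each k+1 search is additionally warm-started from the best k-solution
    plus the data point with the largest residual, which guarantees the
    scree is non-increasing.  The advisory elbow is the k with the largest
    second difference of the RSS curve.
    """
    X = np.asarray(X, dtype=float)
    if kmax >= X.shape[0]:
        raise ValueError("kmax must be below the number of points")
    model = ArchetypalAnalysis(X)
    rss = {}
    sols = {}
    prev_sol = None
    for k in range(1, kmax + 1):
        extra = []
        if prev_sol is not None:
            resid = ((X - prev_sol.A @ prev_sol.Z) ** 2).sum(axis=1)
            extra.append(np.vstack([prev_sol.Z, X[int(np.argmax(resid))]]))
        sol = model.fit(k, nrep=nrep, seed=None if seed is None else seed + k,
                        extra_inits=extra)
        rss[k] = sol.rss
        sols[k] = sol
        prev_sol = sol
    ks = sorted(rss)
    elbow = None
    if len(ks) >= 3:
        # advisory elbow: largest second difference of log-RSS (log scale so
        # a near-zero plateau after a sharp drop dominates absolute drops)
        floor = max(max(rss.values()) * 1e-12, 1e-300)
        lr = {k: np.log(max(rss[k], floor)) for k in ks}
        second = {k: lr[k - 1] - 2 * lr[k] + lr[k + 1] for k in ks[1:-1]}
        elbow = max(second, key=second.get)
    return {"rss": rss, "solutions": sols, "elbow": elbow}


def assign_archetype(X, sol: ArchetypeSolution) -> tuple[np.ndarray, np.ndarray]:
    """Per-plant archetype labels and simplex weights for (new) data.

    Returns ``(labels, weights)``; labels are argmax weights with ties
    broken toward the lowest archetype index.
    """
    W = ArchetypalAnalysis(np.atleast_2d(np.asarray(X, dtype=float))).transform(
        np.atleast_2d(np.asarray(X, dtype=float)), sol
    )
    return np.argmax(W, axis=1), W
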