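"""Variance components and half-sib heritability across families.

The genetic design is a set of families sharing a common parent.  A one-way
random-effects model partitions each trait's variance into an among-family
component σ²_F and a residual σ²_ε.  Under half-sib theory the additive
genetic variance is four times the family variance (σ²_A = 4σ²_F), so
narrow-sense heritability is h² = 4σ²_F / (σ²_F + σ²_ε).

The primary estimator is the closed-form method of moments from the one-way
ANOVA expected mean squares, with the unbalanced-design coefficient
n₀ = (N − Σnᵢ²/N)/(k−1); REML (via statsmodels MixedLM) is available as a
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "HalfSibFamilyModel",
    "variance_components",
    "half_sib_h2",
    "family_summary",
]


@dataclass
class VarianceComponents:
    """Estimated one-way variance components for a single trait."""

    sigma2_family: float
    sigma2_residual: float
    n_families: int
    n_total: int
    estimator: str            # "MoM" or "REML"
    clamped: bool = False     # True when a negative MoM σ²_F was set to 0

    def h2(self, multiplier: float = 4.0, cap: bool = True) -> float:
        """Heritability from the components; see :func:`half_sib_h2`."""
        return half_sib_h2(self, multiplier=multiplier, cap=cap)

    @property
    def h2_uncapped(self) -> float:
        return self.h2(cap=False)


class HalfSibFamilyModel:
    """One-way random-effects model of a trait over common-parent families.

    Parameters
    ----------
    values : 1-D trait values.
    family_ids : matching family labels.

    ``fit()`` returns :class:`VarianceComponents`; ``fit(method="REML")``
    uses a mixed model with a random family intercept instead of the
    closed-form moments estimator.
    """

    def __init__(self, values, family_ids):
        values = np.asarray(values, dtype=float).ravel()
        family_ids = np.asarray(family_ids).ravel()
        if values.shape != family_ids.shape:
            raise ValueError("values and family_ids must have equal length")
        ok = np.isfinite(values)
        values, family_ids = values[ok], family_ids[ok]
        fams, codes = np.unique(family_ids, return_inverse=True)
        if fams.size < 2:
            raise ValueError("need at least two families")
        if values.size < 2 * fams.size:
            raise ValueError("need >= 2 observations per family on average")
        self.values = values
        self.codes = codes
        self.k = int(fams.size)

    def _fit_mom(self) -> VarianceComponents:
        y, g, k = self.values, self.codes, self.k
        N = y.size
        counts = np.bincount(g, minlength=k).astype(float)
        sums = np.bincount(g, weights=y, minlength=k)
        means = sums / counts
        grand = y.mean()
        ssb = float(np.sum(counts * (means - grand) ** 2))
        ssw = float(np.sum((y - means[g]) ** 2))
        msb = ssb / (k - 1)
        msw = ssw / (N - k)
        n0 = (N - np.sum(counts**2) / N) / (k - 1)
        raw = (msb - msw) / n0
        clamped = raw < 0
        return VarianceComponents(
            sigma2_family=max(0.0, raw),
            sigma2_residual=msw,
            n_families=k,
            n_total=int(N),
            estimator="MoM",
            clamped=bool(clamped),
        )

    def _fit_reml(self) -> VarianceComponents:
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": self.values, "fam": self.codes})
        m = smf.mixedlm("y ~ 1", df, groups=df["fam"]).fit(reml=True)
        return VarianceComponents(
            sigma2_family=float(m.cov_re.iloc[0, 0]),
            sigma2_residual=float(m.scale),
            n_families=self.k,
            n_total=int(self.values.size),
            estimator="REML",
        )

    def fit(self, method: str = "MoM") -> VarianceComponents:
        method = method.upper()
        if method == "MOM":
            return self._fit_mom()
        if method == "REML":
            return self._fit_reml()
        raise ValueError(f"unknown estimator {method!r}")


def variance_components(values, family_ids, estimator: str = "MoM") -> VarianceComponents:
    """Functional form of :class:`HalfSibFamilyModel`."""
    return HalfSibFamilyModel(values, family_ids).fit(estimator)


def half_sib_h2(vc: VarianceComponents, multiplier: float = 4.0,
                cap: bool = True) -> float:
    """Half-sib heritability h² = multiplier·σ²_F / (σ²_F + σ²_ε).

    The default multiplier 4 is the half-sib assumption; 2 gives the
    full-sib sensitivity variant.  With ``cap=True`` (default) estimates
    above 1 — possible through sampling noise — are truncated to 1.
    """
    tot = vc.sigma2_family + vc.sigma2_residual
    if tot == 0:
        raise ValueError("heritability undefined: both components are zero")
    h2 = multiplier * vc.sigma2_family / tot
    return min(1.0, h2) if cap else h2


def family_summary(df: pd.DataFrame, trait: str, family_col: str = "family",
                   exclude_families: tuple = ()) -> dict:
    """Per-family mean/SE/CV and population mean, range, CV for one trait.

    ``exclude_families`` removes entries (e.g. the common parent's own
    plots) from the population-level statistics; they still appear in the
    per-family table.
    """
    sub = df[[family_col, trait]].dropna()
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    per = sub.groupby(family_col)[trait].agg(["mean", "sem", "std", "count"])
    with np.errstate(divide="ignore", invalid="ignore"):
        per["cv"] = per["std"] / per["mean"]
    pop = sub[~sub[family_col].isin(exclude_families)][trait]
    mean = float(pop.mean())
    cv = float(pop.std(ddof=1) / mean) if mean != 0 else float("nan")
    return {
        "per_family": per,
        "population": {
            "mean": mean,
            "min": float(pop.min()),
            "max": float(pop.max()),
            "cv": cv,
            "n": int(pop.size),
        },
    }
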