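"""Two-dimensional canopy "kite" model and derived architecture traits.

A plant's canopy outline is summarised as a kite (a quadrilateral symmetric
about the primary stem) built from four field measurements: plant height
(HT), maximum canopy diameter (MCD), the height at which that diameter
occurs (MCDH), and trunk length to the first branch (TRKL).  The kite's
vertices sit at (0, TRKL) bottom, (0, HT) top, and (±MCD/2, MCDH) laterally;
the trunk below the first branch is excluded.  From the kite we derive area,
perimeter, circularity, the upper/lower hypotenuse ratio, the branch angle
of the lower triangle, and a bicone-of-revolution canopy volume.

All lengths are carried in centimetres internally; area, perimeter and
volume are reported in m², m and m³ at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArchitectureMeasurements",
    "KiteModel",
    "build_kite",
    "kite_branch_angle",
    "kite_volume",
    "canopy_density",
    "specific_kite_area",
    "floral_biomass_per_area",
    "internode_length",
    "shape_ratios",
    "derive_kite_traits",
]

CM2_PER_M2 = 1e4
CM3_PER_M3 = 1e6
CM_PER_M = 100.0


class KiteValidationError(ValueError):
    """A measurement set that cannot form a valid (non-degenerate) kite."""


@dataclass(frozen=True)
class ArchitectureMeasurements:
    """Raw architecture measurements for one plant (cm, counts).

    Parameters
    ----------
    ht : plant height, length of the primary stem (cm).
    mcd : maximum canopy diameter (cm).
    mcdh : height at the maximum canopy diameter (cm).
    trkl : trunk length from the ground to the first branch (cm).
    dia : basal stem diameter (cm), optional.
    bpair : branching pairs per 50 cm of primary stem, optional.
    """

    ht: float
    mcd: float
    mcdh: float
    trkl: float = 0.0
    dia: float | None = None
    bpair: float | None = None

    def validate(self) -> None:
        if not self.ht > 0:
            raise KiteValidationError(f"ht must be positive, got {self.ht}")
        if not self.mcd > 0:
            raise KiteValidationError(f"mcd must be positive, got {self.mcd}")
        if self.trkl < 0:
            raise KiteValidationError(f"trkl must be non-negative, got {self.trkl}")
        if self.mcdh <= self.trkl:
            raise KiteValidationError(
                f"mcdh ({self.mcdh}) must exceed trkl ({self.trkl}): "
                "lower kite leg would be degenerate"
            )
        if self.mcdh >= self.ht:
            raise KiteValidationError(
                f"mcdh ({self.mcdh}) must be below ht ({self.ht}): "
                "upper kite leg would be degenerate"
            )


@dataclass(frozen=True)
class KiteModel:
    """Derived kite geometry.  Legs and hypotenuses in cm; A/P/V in m²/m/m³."""

    lower_leg: float      # a = mcdh - trkl (cm)
    upper_leg: float      # b = ht - mcdh (cm)
    half_width: float     # w = mcd / 2 (cm)
    lower_hyp: float      # sqrt(w² + a²) (cm)
    upper_hyp: float      # sqrt(w² + b²) (cm)
    area: float           # ½·(a+b)·2w, in m²
    perimeter: float      # 2·(h_l + h_u), in m
    circularity: float    # 4πA/P², dimensionless, ≤ π/4
    hyp_ratio: float      # KHR = h_u / h_l
    branch_angle: float   # KBA = arctan(w/a), degrees
    volume: float         # bicone (π/3)·w²·(a+b), in m³


def build_kite(m: ArchitectureMeasurements) -> KiteModel:
    """Construct the kite model from one plant's architecture measurements.

    Raises
    ------
    KiteValidationError
        If the measurements violate ``trkl < mcdh < ht`` or are non-positive,
        naming the offending field.
    """
    m.validate()
    a = m.mcdh - m.trkl
    b = m.ht - m.mcdh
    w = m.mcd / 2.0
    h_l = math.hypot(w, a)
    h_u = math.hypot(w, b)
    area_cm2 = 0.5 * (a + b) * (2.0 * w)          # ½·d_vertical·d_horizontal
    per_cm = 2.0 * (h_l + h_u)
    circ = 4.0 * math.pi * area_cm2 / per_cm**2   # unit-free
    return KiteModel(
        lower_leg=a,
        upper_leg=b,
        half_width=w,
        lower_hyp=h_l,
        upper_hyp=h_u,
        area=area_cm2 / CM2_PER_M2,
        perimeter=per_cm / CM_PER_M,
        circularity=circ,
        hyp_ratio=h_u / h_l,
        branch_angle=math.degrees(math.atan2(w, a)),
        volume=(math.pi / 3.0) * w**2 * (a + b) / CM3_PER_M3,
    )


def kite_branch_angle(k: KiteModel) -> float:
    """Branch angle (degrees) between the primary stem and the lower kite
    hypotenuse: arctan(w / a) from the lower kite triangle."""
    if k.lower_leg <= 0:
        raise KiteValidationError("degenerate lower triangle: lower_leg must be > 0")
    return math.degrees(math.atan2(k.half_width, k.lower_leg))


def kite_volume(k: KiteModel) -> float:
    """Canopy volume (m³) as the bicone of revolution of the kite about the
    stem axis: V = (π/3)·w²·(a+b)."""
    return k.volume


def canopy_density(wet_leaf_mass_kg: float, k: KiteModel) -> float:
    """Canopy density (kg m⁻³): wet leaf mass divided by kite volume."""
    if wet_leaf_mass_kg < 0:
        raise ValueError("mass must be non-negative")
    if k.volume <= 0:
        raise ValueError("kite volume must be positive")
    return wet_leaf_mass_kg / k.volume


def specific_kite_area(k: KiteModel, dry_biomass_kg: float) -> float:
    """Specific kite area (m² kg⁻¹): kite area per unit dry biomass.

    Low values indicate small plants with a high dry-biomass proportion.
    """
    if dry_biomass_kg <= 0:
        raise ValueError("dry biomass must be positive")
    return k.area / dry_biomass_kg


def floral_biomass_per_area(dsbm_kg: float, mcd_cm: float) -> float:
    """Dry floral biomass per unit ground area (kg m⁻²): DSBM divided by the
    square of the maximum canopy diameter."""
    if mcd_cm <= 0:
        raise ValueError("mcd must be positive")
    return dsbm_kg / (mcd_cm / CM_PER_M) ** 2


def internode_length(bpair: float) -> float:
    """Internode length (cm) from the count of branching pairs along 50 cm of
    the primary stem: 50 / bpair."""
    if bpair < 1:
        raise ValueError(f"bpair must be >= 1, got {bpair}")
    return 50.0 / bpair


def shape_ratios(m: ArchitectureMeasurements) -> tuple[float, float]:
    """The two dimensionless canopy-shape ratios used for archetypal
    classification: (MCD/HT, MCDH/HT).

    A first ratio above 1 indicates a prostrate habit (canopy wider than
    tall).
    """
    if m.ht <= 0:
        raise KiteValidationError(f"ht must be positive, got {m.ht}")
    return m.mcd / m.ht, m.mcdh / m.ht


def symmetric_kite_circularity(branch_angle_deg: np.ndarray) -> np.ndarray:
    """Circularity of the symmetric kite (equal legs, a = b) as a function of
    its branch angle.  Closed form: C = (π/2)·sin(θ)·cos(θ) = (π/4)·sin(2θ),
    maximal (π/4) at 45°."""
    theta = np.radians(np.asarray(branch_angle_deg, dtype=float))
    return (math.pi / 4.0) * np.sin(2.0 * theta)


def max_circularity_search(n_grid: int = 2000) -> tuple[float, float]:
    """Grid-search the branch angle maximizing circularity over symmetric
    kites (KHR = 1).

    Returns
    -------
    (angle_deg, circularity) at the grid argmax.  With the default grid the
    argmax is 45° to well under 0.1° and the maximum is π/4.
    """
    angles = np.linspace(0.0, 90.0, n_grid + 1)[1:-1]
    circ = np.empty_like(angles)
    for i, ang in enumerate(angles):
        a = 50.0
        w = a * math.tan(math.radians(ang))
        k = build_kite(
            ArchitectureMeasurements(ht=2 * a, mcd=2 * w, mcdh=a, trkl=0.0)
        )
        circ[i] = k.circularity
    j = int(np.argmax(circ))
    return float(angles[j]), float(circ[j])


# Column names follow the trait-table abbreviations (HT, MCD, ... KC).
def derive_kite_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived kite traits to a per-plant trait table.

    Requires columns HT, MCD, MCDH, TRKL (cm).  Adds KITE (m²), KHR, KBA (°),
    KC, VOL_KITE (m³), and, when BPAIR is present, INL (cm).  Rows violating
    the kite preconditions get NaN derived traits.
    """
    out = df.copy()
    cols = {"KITE": [], "KHR": [], "KBA": [], "KC": [], "VOL_KITE": []}
    for _, row in df.iterrows():
        try:
            k = build_kite(
                ArchitectureMeasurements(
                    ht=row["HT"], mcd=row["MCD"], mcdh=row["MCDH"],
                    trkl=row.get("TRKL", 0.0),
                )
            )
            vals = (k.area, k.hyp_ratio, k.branch_angle, k.circularity, k.volume)
        except (KiteValidationError, KeyError):
            vals = (np.nan,) * 5
        for c, v in zip(cols, vals):
            cols[c].append(v)
    for c, v in cols.items():
        out[c] = v
    if "BPAIR" in df.columns:
        out["INL"] = [
            internode_length(b) if b >= 1 else np.nan for b in df["BPAIR"]
        ]
    return out
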