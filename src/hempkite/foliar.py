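"""Derived foliar traits: leaflet area, specific leaf/petiole area, leafing
intensity, primary stem volume, and the green leaf index from leaf scans."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoliarMeasurements",
    "pointed_oval_area",
    "specific_area",
    "stem_volume",
    "leafing_intensity",
    "green_leaf_index",
]


@dataclass(frozen=True)
class FoliarMeasurements:
    """One plant's foliar measurements (cm², g, cm, counts)."""

    leaf_area: float = np.nan
    leaf_dry_weight: float = np.nan
    petiole_area: float = np.nan
    petiole_dry_weight: float = np.nan
    leaf_perimeter: float = np.nan
    leaf_length: float = np.nan
    middle_leaflet_width: float = np.nan
    leaflet_number: float = np.nan
    leaf_count: float = np.nan

    def __post_init__(self):
        for name in (
            "leaf_area", "leaf_dry_weight", "petiole_area",
            "petiole_dry_weight", "leaf_perimeter", "leaf_length",
            "middle_leaflet_width",
        ):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        n = self.leaflet_number
        if np.isfinite(n) and (n < 3 or n % 2 == 0):
            warnings.warn(
                f"leaflet_number {n} is atypical (expected odd and >= 3)",
                stacklevel=2,
            )


def pointed_oval_area(length_cm: float, width_cm: float) -> float:
    """Area (cm²) of a pointed oval (parabolic lens): (2/3)·length·width.

    Used for middle-leaflet area from its maximum length and width.
    """
    if length_cm < 0 or width_cm < 0:
        raise ValueError("length and width must be non-negative")
    return (2.0 / 3.0) * length_cm * width_cm


def specific_area(area_cm2: float, dry_weight_g: float) -> float:
    """Specific area (cm² g⁻¹): tissue area per unit dry mass.

    Computes SLA from leaf inputs and SPA from petiole inputs.
    """
    if dry_weight_g <= 0:
        raise ValueError("dry weight must be positive")
    if area_cm2 < 0:
        raise ValueError("area must be non-negative")
    return area_cm2 / dry_weight_g


def stem_volume(dia_cm: float, ht_cm: float) -> float:
    """Primary stem volume (cm³) modelled as a cone on the basal diameter:
    (1/3)·π·(dia/2)²·ht."""
    if dia_cm <= 0 or ht_cm <= 0:
        raise ValueError("diameter and height must be positive")
    return (math.pi / 3.0) * (dia_cm / 2.0) ** 2 * ht_cm


def leafing_intensity(leaf_count: float, stem_volume_cm3: float) -> float:
    """Leafing intensity (count cm⁻³): number of leaves per unit stem volume."""
    if stem_volume_cm3 <= 0:
        raise ValueError("stem volume must be positive")
    if leaf_count < 0:
        raise ValueError("leaf count must be non-negative")
    return leaf_count / stem_volume_cm3


def green_leaf_index(rgb: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean green leaf index over masked pixels: (2G−R−B)/(2G+R+B).

    Parameters
    ----------
    rgb : (H, W, 3) array, channels on a common scale.
    mask : (H, W) boolean foreground mask; ``None`` means all pixels.

    Pixels with zero denominator are excluded (their count is reported in a
    warning when any occur).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be an (H, W, 3) array")
    if mask is None:
        mask = np.ones(rgb.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    r, g, b = (rgb[..., i][mask] for i in range(3))
    denom = 2.0 * g + r + b
    ok = denom != 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-denominator pixels", stacklevel=2)
    if not ok.any():
        raise ValueError("no pixels with nonzero denominator")
    gli = (2.0 * g[ok] - r[ok] - b[ok]) / denom[ok]
    return float(gli.mean())
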