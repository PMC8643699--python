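"""Powdery-mildew severity summaries: area under the disease progress curve.

Severity is the visually rated percentage of canopy leaf area diseased
(0–100%), assessed at a few dates; AUDPC is its trapezoidal integral over
time (units %·days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SeveritySeries", "audpc", "DEFAULT_ASSESSMENT_DAYS"]

DEFAULT_ASSESSMENT_DAYS = (71.0, 86.0, 97.0)


@dataclass(frozen=True)
class SeveritySeries:
    """Disease severity ratings (%) at assessment days (DAP)."""

    days: np.ndarray
    severities: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        sev = np.asarray(self.severities, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "severities", sev)
        if days.shape != sev.shape or days.ndim != 1:
            raise ValueError("days and severities must be 1-D, equal length")
        if not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any((sev < 0) | (sev > 100)):
            raise ValueError("severities must lie in [0, 100]")


def audpc(s: SeveritySeries, relative: bool = False) -> float:
    """Absolute AUDPC: trapezoidal integral of severity over assessment days.

    With ``relative=True`` the integral is divided by its upper bound
    100·(t_last − t_first), giving a value in [0, 1].
    """
    if s.days.size < 2:
        raise ValueError("AUDPC needs at least two time points")
    value = float(np.trapezoid(s.severities, s.days))
    if relative:
        value /= 100.0 * (s.days[-1] - s.days[0])
    return value
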