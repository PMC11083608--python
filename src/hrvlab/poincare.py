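"""Poincare-plot quantification of beat-to-beat dynamics.

Each pair (RR(n), RR(n+1)) is a point; SD1 is the dispersion perpendicular
to the identity line (short-term variability), SD2 the dispersion along it
(long-term variability).  With x = RR(1..n-1), y = RR(2..n):

    SD1 = population sd of (y - x)/sqrt(2)
    SD2 = population sd of (y + x)/sqrt(2)

Population (1/n) normalization is used so that SD1 = RMSSD/sqrt(2) holds
exactly whenever the mean successive difference is zero (this differs from
the sample-sd convention used for SDNN in the time-domain module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import RrSeries, register_report

__all__ = ["PoincareReport", "poincare"]


@register_report
@dataclass
class PoincareReport:
    """SD1/SD2 in ms; ``points`` is the (n-1, 2) array of (RR(n), RR(n+1))."""

    sd1: float
    sd2: float
    ratio: float | None
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    lag: int = 1


def poincare(rr: RrSeries, lag: int = 1) -> PoincareReport:
    """Quantify the lag-``lag`` Poincare plot (the conventional plot has lag 1)."""
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    x_all = rr.intervals
    if x_all.size < lag + 2:
        raise ValidationError("need at least lag + 2 intervals")
    x = x_all[:-lag]
    y = x_all[lag:]
    sd1 = float(np.std((y - x) / np.sqrt(2.0), ddof=0))
    sd2 = float(np.std((y + x) / np.sqrt(2.0), ddof=0))
    # Clamp pure round-off (pairwise-summation residue on constant input).
    tiny = 1e-12 * float(np.abs(x_all).max())
    sd1 = 0.0 if sd1 < tiny else sd1
    sd2 = 0.0 if sd2 < tiny else sd2
    ratio = sd1 / sd2 if sd2 > 0 else None
    return PoincareReport(sd1=sd1, sd2=sd2, ratio=ratio,
                          points=np.column_stack((x, y)), lag=lag)
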