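"""Phase-space reconstruction diagnostics: AMI delay, FNN dimension, attractor.

A scalar series is embedded as (x(t), x(t+tau), ..., x(t+(m-1)tau)).  The
delay ``tau`` is chosen at the first local minimum of the average mutual
information (AMI) between x(t) and x(t+tau); the dimension ``m`` by the
false-nearest-neighbors (FNN) criterion of Kennel et al.: a neighbor in
dimension m is false when adding the (m+1)-th coordinate stretches the
distance by more than ``rtol``, or moves the pair further apart than
``atol`` times the series sd.  ``m_opt`` is the first dimension whose FNN
percentage drops to/below a threshold (default 1%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import register_report
from .recurrence import embed

__all__ = [
    "AmiResult",
    "FnnResult",
    "EmbeddingReport",
    "ami",
    "fnn",
    "attractor3d",
    "embedding_report",
]


@register_report
@dataclass
class AmiResult:
    """AMI (nats) per lag 0..tau_max and the chosen delay."""

    ami_curve: np.ndarray
    tau_opt: int


@register_report
@dataclass
class FnnResult:
    """FNN percentage per dimension 1..m_max and the chosen dimension."""

    fnn_curve: np.ndarray
    m_opt: int


@register_report
@dataclass
class EmbeddingReport:
    """Combined phase-space diagnostics for one series."""

    ami_curve: np.ndarray
    tau_opt: int
    fnn_curve: np.ndarray
    m_opt: int
    attractor3d: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


def ami(x: np.ndarray, tau_max: int = 50, bins: int = 4,
        min_prominence: float = 0.1) -> AmiResult:
    """Average mutual information of (x(t), x(t+tau)) for tau = 0..tau_max.

    MI is estimated from a ``bins`` x ``bins`` equal-width 2-D histogram, in
    nats.  ``tau_opt`` is the first local minimum of the curve whose
    prominence is at least ``min_prominence`` times the curve's range; if the
    curve has no such minimum, the global minimum is returned with a warning.

    The coarse 4-bin default partition keeps the curve smooth for strongly
    periodic signals; finer partitions resolve more structure but develop
    bin-resonance wiggles that produce spurious shallow minima (the
    prominence requirement guards against those as well).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= tau_max + 10:
        raise ValidationError("series too short for the requested tau_max")
    if np.ptp(x) == 0:
        raise ValidationError("AMI undefined for a constant series")
    edges = np.linspace(x.min(), x.max(), bins + 1)
    curve = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        a = x[: x.size - tau]
        b = x[tau:]
        joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        curve[tau] = float(np.sum(p[mask] * np.log(p[mask] /
                                                   (px @ py)[mask])))
    prominence = min_prominence * float(np.ptp(curve))
    minima, _ = find_peaks(-curve, prominence=prominence if prominence > 0
                           else None)
    if minima.size:
        tau_opt = int(minima[0])
    else:
        tau_opt = int(np.argmin(curve[1:]) + 1)
        warnings.warn("AMI curve has no prominent local minimum; using the "
                      "global minimum", stacklevel=2)
    return AmiResult(ami_curve=curve, tau_opt=tau_opt)


def fnn(x: np.ndarray, tau: int, m_max: int = 8, rtol: float = 15.0,
        atol: float = 2.0, threshold_pct: float = 1.0,
        theiler: int | None = None) -> FnnResult:
    """False-nearest-neighbor fraction per embedding dimension 1..m_max.

    ``m_opt`` is the first dimension with FNN <= ``threshold_pct``; when the
    curve never drops that low, the dimension with the smallest FNN is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValidationError("tau must be >= 1")
    if x.size <= m_max * tau + 10:
        raise ValidationError("series too short for the requested m_max")
    sd = float(x.std())
    if sd == 0:
        raise ValidationError("FNN undefined for a constant series")
    theiler = tau if theiler is None else theiler
    curve = np.empty(m_max)
    for m in range(1, m_max + 1):
        # Vectors must leave room for the (m+1)-th coordinate x[i + m*tau].
        n = x.size - m * tau
        v = embed(x[: x.size - tau], m, tau)[:n]
        nxt = x[m * tau: m * tau + n]
        tree = cKDTree(v)
        k = min(theiler * 2 + 2, n)
        dists, idxs = tree.query(v, k=k)
        # Distances below this floor are duplicates up to round-off; the
        # ratio test is meaningless there and the absolute criterion decides.
        zero_floor = 1e-9 * sd
        false = 0
        counted = 0
        for i in range(n):
            j = -1
            for col in range(1, k):
                cand = int(idxs[i, col])
                if abs(cand - i) > theiler:
                    j = cand
                    d = float(dists[i, col])
                    break
            if j < 0:
                continue
            counted += 1
            extra = abs(nxt[i] - nxt[j])
            if d <= zero_floor:
                # Duplicate point: next-nearest distinct neighbor if any.
                alt = None
                for col in range(1, k):
                    cand = int(idxs[i, col])
                    if abs(cand - i) > theiler and dists[i, col] > zero_floor:
                        alt = (int(cand), float(dists[i, col]))
                        break
                if alt is None:
                    if extra > atol * sd:
                        false += 1
                    continue
                j, d = alt
                extra = abs(nxt[i] - nxt[j])
            expanded = np.hypot(d, extra)
            if extra / d > rtol or expanded / sd > atol:
                false += 1
        curve[m - 1] = 100.0 * false / counted if counted else np.nan
    below = np.flatnonzero(curve <= threshold_pct)
    if below.size:
        m_opt = int(below[0]) + 1
    else:
        m_opt = int(np.nanargmin(curve)) + 1
        warnings.warn(
            f"FNN never dropped to {threshold_pct}%; returning the dimension "
            "with the smallest fraction", stacklevel=2)
    return FnnResult(fnn_curve=curve, m_opt=m_opt)


def attractor3d(x: np.ndarray, tau: int) -> np.ndarray:
    """Delay-embedding triples (x(t), x(t+tau), x(t+2*tau)) for 3-D plotting."""
    x = np.asarray(x, dtype=float)
    if tau <= 0:
        raise ValidationError("tau must be >= 1")
    if x.size <= 2 * tau:
        raise ValidationError("series too short for a 3-D embedding")
    return embed(x, 3, tau)


def embedding_report(x: np.ndarray, tau_max: int = 50, m_max: int = 8,
                     bins: int = 16, rtol: float = 15.0, atol: float = 2.0
                     ) -> EmbeddingReport:
    """AMI + FNN + 3-D attractor for one series (tau from AMI feeds FNN)."""
    x = np.asarray(x, dtype=float)
    tau_max = min(tau_max, max(1, x.size // 4))
    ami_res = ami(x, tau_max=tau_max, bins=bins)
    m_max_eff = max(2, min(m_max, (x.size - 11) // max(ami_res.tau_opt, 1)))
    fnn_res = fnn(x, tau=ami_res.tau_opt, m_max=m_max_eff, rtol=rtol, atol=atol)
    return EmbeddingReport(
        ami_curve=ami_res.ami_curve, tau_opt=ami_res.tau_opt,
        fnn_curve=fnn_res.fnn_curve, m_opt=fnn_res.m_opt,
        attractor3d=attractor3d(x, ami_res.tau_opt),
    )
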