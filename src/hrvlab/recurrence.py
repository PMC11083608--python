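"""Recurrence-plot construction and quantification (RQA).

The series is delay-embedded with dimension ``m`` and delay ``tau``; the
recurrence matrix marks pairs of embedded states closer than a threshold
``epsilon``.  Quantifiers (line of identity always excluded):

* REC — percentage of recurrent points among the N^2 - N off-identity cells;
* DET — percentage of recurrent points lying on diagonal lines of length at
  least ``l_min`` (deterministic, periodicity-like structure);
* LAM — percentage of recurrent points on vertical lines of length at least
  ``v_min`` (laminar, stationary episodes); the matrix is symmetric so
  vertical and horizontal counts coincide;
* ENTR — Shannon entropy (nats) of the distribution of diagonal line
  lengths >= ``l_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io import RrSeries, register_report

__all__ = [
    "RqaConfig",
    "RecurrenceReport",
    "embed",
    "recurrence_matrix",
    "rqa",
    "rqa_from_rr",
]


@dataclass(frozen=True)
class RqaConfig:
    """RQA settings.

    ``m``/``tau`` default to None, meaning "derive per record from the
    phase-space diagnostics" (first AMI minimum for tau, FNN for m).
    ``epsilon_frac`` scales the threshold to the maximum pairwise distance of
    the embedded cloud; set ``epsilon`` to use a fixed threshold instead.
    """

    m: int | None = None
    tau: int | None = None
    epsilon: float | None = None
    epsilon_frac: float = 0.1
    norm: str = "euclidean"
    l_min: int = 2
    v_min: int = 2

    def __post_init__(self) -> None:
        if self.norm not in ("euclidean", "max"):
            raise ValidationError("norm must be 'euclidean' or 'max'")
        if self.l_min < 2 or self.v_min < 2:
            raise ValidationError("l_min and v_min must be >= 2")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")


@register_report
@dataclass
class RecurrenceReport:
    """RQA result; rec/det/lam in %, entr in nats, histograms as {length: count}."""

    rec: float
    det: float | None
    lam: float | None
    entr: float | None
    diag_hist: dict = field(default_factory=dict)
    vert_hist: dict = field(default_factory=dict)
    n_points: int = 0
    settings: dict = field(default_factory=dict)


def embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed a scalar series into (n - (m-1)*tau, m) state vectors."""
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise ValidationError("m and tau must be >= 1")
    n = x.size - (m - 1) * tau
    if n < 2:
        raise ValidationError(
            f"series of length {x.size} too short for m={m}, tau={tau}"
        )
    return np.column_stack([x[k * tau: k * tau + n] for k in range(m)])


def recurrence_matrix(x: np.ndarray, m: int = 1, tau: int = 1,
                      epsilon: float = 0.1, norm: str = "euclidean"
                      ) -> np.ndarray:
    """Boolean recurrence matrix: R[i, j] = 1 iff ||v_i - v_j|| <= epsilon."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    v = embed(x, m, tau)
    metric = "euclidean" if norm == "euclidean" else "chebyshev"
    dist = squareform(pdist(v, metric=metric))
    return dist <= epsilon


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges[1::2] - edges[0::2]


def rqa(matrix: np.ndarray, l_min: int = 2, v_min: int = 2,
        settings: dict | None = None) -> RecurrenceReport:
    """Quantify a recurrence matrix; the line of identity is excluded throughout."""
    matrix = np.asarray(matrix, dtype=bool)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("recurrence matrix must be square")
    if not (matrix == matrix.T).all():
        raise ValidationError("recurrence matrix must be symmetric")
    n = matrix.shape[0]
    off = matrix.copy()
    np.fill_diagonal(off, False)
    recurrent = int(off.sum())
    rec = 100.0 * recurrent / (n * n - n) if n > 1 else 0.0

    if recurrent == 0:
        return RecurrenceReport(rec=0.0, det=None, lam=None, entr=None,
                                diag_hist={}, vert_hist={}, n_points=n,
                                settings=settings or {})

    # Diagonal line-length histogram over all off-identity diagonals
    # (both triangles, so a single structure is counted twice, symmetric).
    diag_lengths: list[int] = []
    for k in range(1, n):
        for lengths in (_run_lengths(np.diagonal(off, offset=k)),
                        _run_lengths(np.diagonal(off, offset=-k))):
            diag_lengths.extend(lengths.tolist())
    diag_lengths = np.asarray(diag_lengths, dtype=int)
    diag_long = diag_lengths[diag_lengths >= l_min]
    det = 100.0 * diag_long.sum() / recurrent

    vert_lengths: list[int] = []
    for j in range(n):
        vert_lengths.extend(_run_lengths(off[:, j]).tolist())
    vert_lengths = np.asarray(vert_lengths, dtype=int)
    vert_long = vert_lengths[vert_lengths >= v_min]
    lam = 100.0 * vert_long.sum() / recurrent

    if diag_long.size:
        values, counts = np.unique(diag_long, return_counts=True)
        p = counts / counts.sum()
        entr = float(-(p * np.log(p)).sum())
        diag_hist = {int(v): int(c) for v, c in zip(values, counts)}
    else:
        entr = None
        diag_hist = {}
    if vert_long.size:
        vv, vc = np.unique(vert_long, return_counts=True)
        vert_hist = {int(v): int(c) for v, c in zip(vv, vc)}
    else:
        vert_hist = {}

    return RecurrenceReport(rec=float(rec), det=float(det), lam=float(lam),
                            entr=entr, diag_hist=diag_hist,
                            vert_hist=vert_hist, n_points=n,
                            settings=settings or {})


def rqa_from_rr(rr: RrSeries, cfg: RqaConfig | None = None) -> RecurrenceReport:
    """Embed an RR series and quantify its recurrence structure.

    When ``cfg.m``/``cfg.tau`` are None they are derived from the series via
    the phase-space diagnostics (first AMI minimum; FNN dimension).  The
    threshold defaults to ``epsilon_frac`` times the maximum pairwise
    distance of the embedded cloud.
    """
    cfg = cfg or RqaConfig()
    if rr.n_intervals < 50:
        raise ValidationError("need at least 50 intervals for RQA")
    x = rr.intervals
    tau = cfg.tau
    m = cfg.m
    if tau is None or m is None:
        from .phase_space import ami, fnn
        if tau is None:
            tau_max = min(50, x.size // 4)
            tau = ami(x, tau_max=tau_max).tau_opt
        if m is None:
            m_max = max(2, min(8, (x.size - 10) // max(tau, 1)))
            m = fnn(x, tau=tau, m_max=m_max).m_opt
    v = embed(x, m, tau)
    metric = "euclidean" if cfg.norm == "euclidean" else "chebyshev"
    dist = squareform(pdist(v, metric=metric))
    epsilon = cfg.epsilon if cfg.epsilon is not None else (
        cfg.epsilon_frac * float(dist.max())
    )
    if epsilon <= 0:
        epsilon = np.finfo(float).tiny  # constant series: everything recurs
    matrix = dist <= epsilon
    return rqa(matrix, l_min=cfg.l_min, v_min=cfg.v_min, settings={
        "m": int(m), "tau": int(tau), "epsilon": float(epsilon),
        "norm": cfg.norm, "l_min": cfg.l_min, "v_min": cfg.v_min,
        "theiler": 1,
    })
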