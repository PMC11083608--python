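"""Time-domain and geometric HRV indices.

Implements the conventional (Task-Force) definitions: SDNN as the sample sd
of all NN intervals over the whole record; SDANN as the sd of 5-min segment
means; SDNN Index as the mean of 5-min segment sds; RMSSD; pNN50 (percent of
successive differences exceeding 50 ms); and the geometric pair HRVTi (total
count over modal bin count) and TINN (base width of the least-squares
triangle fitted to the NN histogram).  The histogram uses the standard
1/128 s = 7.8125 ms bin width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import RrSeries, register_report

__all__ = [
    "HrvTimeReport",
    "RrHistogram",
    "time_domain",
    "rr_histogram",
    "geometric_indices",
    "DEFAULT_BIN_WIDTH_MS",
    "SEGMENT_SECONDS",
]

DEFAULT_BIN_WIDTH_MS = 7.8125  # 1/128 s
SEGMENT_SECONDS = 300.0


@register_report
@dataclass
class HrvTimeReport:
    """Time-domain HRV result bundle; sds in ms, pnn50 in %, hrv_ti unitless."""

    mean_rr: float
    sdnn: float
    sdann: float | None
    rmssd: float
    sdnn_index: float | None
    pnn50: float
    hrv_ti: float
    tinn: float
    n_intervals: int
    segment_count: int


@register_report
@dataclass
class RrHistogram:
    """Uniform-bin NN-interval histogram (bins aligned to 0 ms)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_intervals(self) -> int:
        return int(np.sum(self.counts))


def time_domain(rr: RrSeries, segment_seconds: float = SEGMENT_SECONDS,
                bin_width: float = DEFAULT_BIN_WIDTH_MS) -> HrvTimeReport:
    """Compute the full time-domain report for an NN series.

    SDANN and SDNN Index require at least two complete ``segment_seconds``
    windows (by beat time, incomplete tail dropped) and are None otherwise.
    """
    if not rr.is_nn:
        warnings.warn("time_domain called on an unfiltered (non-NN) series",
                      stacklevel=2)
    x = rr.intervals
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 intervals")
    diffs = np.diff(x)
    mean_rr = float(x.mean())
    sdnn = float(x.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size)

    # 5-min segmentation by the time at which each interval ends.
    t = rr.interval_times - rr.beat_times[0]
    total = float(rr.beat_times[-1] - rr.beat_times[0])
    segment_count = int(total // segment_seconds)
    sdann = sdnn_index = None
    if segment_count >= 2:
        seg_means, seg_sds = [], []
        for k in range(segment_count):
            mask = (t > k * segment_seconds) & (t <= (k + 1) * segment_seconds)
            seg = x[mask]
            if seg.size >= 2:
                seg_means.append(seg.mean())
                seg_sds.append(seg.std(ddof=1))
        if len(seg_means) >= 2:
            sdann = float(np.std(seg_means, ddof=1))
            sdnn_index = float(np.mean(seg_sds))

    hist = rr_histogram(rr, bin_width=bin_width)
    hrv_ti, tinn = geometric_indices(hist)
    return HrvTimeReport(
        mean_rr=mean_rr, sdnn=sdnn, sdann=sdann, rmssd=rmssd,
        sdnn_index=sdnn_index, pnn50=pnn50, hrv_ti=hrv_ti, tinn=tinn,
        n_intervals=n, segment_count=segment_count,
    )


def rr_histogram(rr: RrSeries, bin_width: float = DEFAULT_BIN_WIDTH_MS
                 ) -> RrHistogram:
    """Histogram of NN intervals with uniform bins aligned to 0 ms."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    x = rr.intervals
    first = int(np.floor(x.min() / bin_width))
    last = int(np.floor(x.max() / bin_width))
    edges = np.arange(first, last + 2) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    return RrHistogram(bin_edges=edges, counts=counts,
                       mode_bin=int(np.argmax(counts)))


def geometric_indices(hist: RrHistogram) -> tuple[float, float]:
    """HRV triangular index and TINN from an interval histogram.

    HRVTi = total interval count / modal bin count.  TINN = M - N, the base
    of the triangle (zero outside [N, M], apex at the mode center with the
    observed mode height) that minimizes the squared error to the histogram;
    N and M are searched by brute force over a half-bin-width grid on either
    side of the mode (extended two bins beyond the observed range).
    """
    counts = hist.counts.astype(float)
    if counts.sum() <= 0:
        raise ValidationError("histogram has no counts")
    mode = int(np.argmax(counts))
    peak = counts[mode]
    hrv_ti = float(counts.sum() / peak)
    if np.count_nonzero(counts) == 1:
        return hrv_ti, 0.0

    width = hist.bin_width
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0
    apex = centers[mode]
    # Candidate base points on a half-bin grid (edges and centers), from two
    # bins left of the histogram up to the mode, and mode to two bins right;
    # half-bin resolution lets an exactly triangular histogram fit with zero
    # error (its zero crossings sit half a bin beyond the outermost centers).
    lo = hist.bin_edges[0] - 2 * width
    hi = hist.bin_edges[-1] + 2 * width
    grid = np.arange(lo, hi + width / 4, width / 2)
    n_cands = grid[grid < apex - width / 4]
    m_cands = grid[grid > apex + width / 4]

    best = (np.inf, 0.0)
    for n_edge in n_cands:
        for m_edge in m_cands:
            tri = np.zeros_like(counts)
            rising = (centers > n_edge) & (centers <= apex)
            falling = (centers > apex) & (centers < m_edge)
            if apex > n_edge:
                tri[rising] = peak * (centers[rising] - n_edge) / (apex - n_edge)
            tri[centers == apex] = peak
            if m_edge > apex:
                tri[falling] = peak * (m_edge - centers[falling]) / (m_edge - apex)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0] - 1e-12:
                best = (err, float(m_edge - n_edge))
    return hrv_ti, best[1]
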