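"""Pan-Tompkins QRS detection and RR/NN series construction.

The detector follows the classic published pipeline: band-pass (5-15 Hz) to
isolate QRS energy, five-point derivative, pointwise squaring, moving-window
integration (150 ms), then adaptive dual-threshold peak picking with a 200 ms
refractory period, 360 ms T-wave discrimination and a search-back pass with a
halved threshold whenever no beat is found within 1.66x the running RR
average.  Each accepted integrator peak is finally localized to the R peak as
the maximum of the input signal within +/-100 ms.

``nn_filter`` turns a raw RR series into normal-to-normal (NN) intervals with
a median-of-five acceptance rule and physiological bounds, returning a
removal log so filtering can be audited against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io import EcgRecord, RrSeries

__all__ = [
    "PanTompkinsConfig",
    "DetectionResult",
    "pan_tompkins",
    "rr_from_peaks",
    "NnFilterConfig",
    "nn_filter",
]


@dataclass(frozen=True)
class PanTompkinsConfig:
    """Constants of the original algorithm; all timing values in seconds."""

    band_lo_hz: float = 5.0
    band_hi_hz: float = 15.0
    band_order: int = 2
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    t_wave_window_s: float = 0.360
    search_back_factor: float = 1.66
    signal_update: float = 0.125   # SPK <- u*peak + (1-u)*SPK
    noise_update: float = 0.125
    threshold_frac: float = 0.25   # THR1 = NPK + frac*(SPK-NPK)
    search_back_frac: float = 0.5  # THR2 = frac*THR1
    r_search_window_s: float = 0.100
    parabolic_refine: bool = False


@dataclass
class DetectionResult:
    """QRS detection output: R-peak positions plus a threshold diagnostic trace."""

    peak_indices: np.ndarray
    peak_times: np.ndarray
    fs: float
    # Diagnostics: one row per candidate integrator peak:
    # (time s, peak height, signal threshold, accepted flag)
    threshold_trace: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    @property
    def n_peaks(self) -> int:
        return self.peak_indices.size


def _band_pass(x: np.ndarray, fs: float, cfg: PanTompkinsConfig) -> np.ndarray:
    sos = sps.butter(cfg.band_order, [cfg.band_lo_hz, cfg.band_hi_hz],
                     btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # Five-point derivative y[n] = (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4]),
    # applied centered so it introduces no net delay.
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    return np.convolve(x, kernel, mode="same")


def _integrate(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    width = max(1, int(round(window_s * fs)))
    return np.convolve(x, np.ones(width) / width, mode="same")


def pan_tompkins(ecg: EcgRecord, cfg: PanTompkinsConfig | None = None
                 ) -> DetectionResult:
    """Detect R peaks; ``ecg`` should already be denoised (see preprocess).

    Records shorter than 5 s are rejected; a zero-variance signal yields an
    empty result.
    """
    cfg = cfg or PanTompkinsConfig()
    fs = ecg.fs
    if fs < 100:
        raise ValidationError("Pan-Tompkins requires fs >= 100 Hz")
    if ecg.duration < 5.0:
        raise ValidationError("record shorter than 5 s")
    x = ecg.samples
    if np.ptp(x) == 0:
        return DetectionResult(peak_indices=np.empty(0, dtype=int),
                               peak_times=np.empty(0), fs=fs)

    filtered = _band_pass(x, fs, cfg)
    integrated = _integrate(_derivative(filtered, fs) ** 2, fs,
                            cfg.integration_window_s)

    refractory = int(round(cfg.refractory_s * fs))
    cand, _ = sps.find_peaks(integrated, distance=max(1, refractory))
    if cand.size == 0:
        return DetectionResult(peak_indices=np.empty(0, dtype=int),
                               peak_times=np.empty(0), fs=fs)

    # Threshold learning phase: first two seconds of the integrated signal.
    learn = integrated[: int(2 * fs)]
    spk = float(learn.max()) * 0.25 if learn.size else float(integrated.max()) * 0.25
    npk = float(learn.mean()) * 0.5 if learn.size else 0.0

    accepted: list[int] = []
    trace: list[tuple[float, float, float, bool]] = []
    rr_recent: list[float] = []

    def threshold1() -> float:
        return npk + cfg.threshold_frac * (spk - npk)

    def accept(peak: int) -> None:
        nonlocal spk
        spk = cfg.signal_update * integrated[peak] + (1 - cfg.signal_update) * spk
        if accepted:
            rr_recent.append((peak - accepted[-1]) / fs)
            del rr_recent[:-8]
        accepted.append(peak)

    def is_t_wave(peak: int) -> bool:
        if not accepted:
            return False
        since = (peak - accepted[-1]) / fs
        if since >= cfg.t_wave_window_s:
            return False
        # Candidate within the T-wave window: compare maximal slopes.
        w = max(2, int(round(0.075 * fs)))
        lo_c = max(0, peak - w)
        lo_p = max(0, accepted[-1] - w)
        slope_c = np.abs(np.diff(filtered[lo_c:peak + w])).max(initial=0.0)
        slope_p = np.abs(np.diff(filtered[lo_p:accepted[-1] + w])).max(initial=0.0)
        return slope_c < 0.5 * slope_p

    i = 0
    while i < cand.size:
        peak = cand[i]
        height = integrated[peak]
        thr1 = threshold1()
        if height > thr1 and not is_t_wave(peak):
            accept(peak)
            trace.append((peak / fs, height, thr1, True))
        else:
            npk = cfg.noise_update * height + (1 - cfg.noise_update) * npk
            trace.append((peak / fs, height, thr1, False))
            # Search-back: no beat within 1.66x the running RR average.
            if accepted and rr_recent:
                rr_avg = float(np.mean(rr_recent))
                if (peak - accepted[-1]) / fs > cfg.search_back_factor * rr_avg:
                    window = cand[(cand > accepted[-1] + refractory) & (cand <= peak)]
                    thr2 = cfg.search_back_frac * thr1
                    back = [c for c in window if integrated[c] > thr2]
                    if back:
                        best = max(back, key=lambda c: integrated[c])
                        accept(best)
                        trace.append((best / fs, integrated[best], thr2, True))
        i += 1

    accepted_arr = np.asarray(sorted(set(accepted)), dtype=int)

    # Localize the R peak as the signal maximum within +/- r_search_window.
    half = int(round(cfg.r_search_window_s * fs))
    peaks = []
    for p in accepted_arr:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peak_indices = np.asarray(sorted(set(peaks)), dtype=int)
    # Enforce the refractory period on the localized peaks.
    if peak_indices.size:
        keep = [0]
        for j in range(1, peak_indices.size):
            if peak_indices[j] - peak_indices[keep[-1]] >= refractory:
                keep.append(j)
            elif x[peak_indices[j]] > x[peak_indices[keep[-1]]]:
                keep[-1] = j
        peak_indices = peak_indices[keep]

    peak_times = peak_indices / fs
    if cfg.parabolic_refine and peak_indices.size:
        peak_times = _parabolic_refine(x, peak_indices, fs)
    return DetectionResult(
        peak_indices=peak_indices,
        peak_times=peak_times,
        fs=fs,
        threshold_trace=np.asarray(trace) if trace else np.empty((0, 4)),
    )


def _parabolic_refine(x: np.ndarray, idx: np.ndarray, fs: float) -> np.ndarray:
    """Sub-sample peak timing via a parabola through the peak and neighbors."""
    times = idx.astype(float)
    inner = (idx > 0) & (idx < x.size - 1)
    i = idx[inner]
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    shift = np.where(denom != 0, 0.5 * (x[i - 1] - x[i + 1]) / denom, 0.0)
    times[inner] = i + np.clip(shift, -0.5, 0.5)
    return times / fs


def rr_from_peaks(det: DetectionResult) -> RrSeries:
    """RR intervals (ms) from successive detected R-peak times; is_nn=False."""
    if det.n_peaks < 2:
        raise ValidationError("need at least 2 peaks to form RR intervals")
    intervals = np.diff(det.peak_times) * 1000.0
    return RrSeries(intervals=intervals, beat_times=det.peak_times.copy(),
                    is_nn=False, label="detected")


@dataclass(frozen=True)
class NnFilterConfig:
    """Normal-to-normal acceptance rule.

    An interval is rejected when it deviates from the median of the previous
    (up to) ``median_window`` accepted intervals by more than ``frac`` of that
    median, or falls outside the physiological range [min_ms, max_ms].
    """

    frac: float = 0.2
    median_window: int = 5
    min_ms: float = 300.0
    max_ms: float = 2000.0


@dataclass
class NnFilterResult:
    series: RrSeries
    removed_indices: np.ndarray
    removal_log: list[tuple[int, float, str]]


def nn_filter(rr: RrSeries, cfg: NnFilterConfig | None = None) -> NnFilterResult:
    """Filter ectopic/artifact intervals; returns NN series plus removal log.

    The NN series is re-timed by the cumulative sum of accepted intervals, so
    downstream segmentation and resampling see a contiguous tachogram.
    """
    cfg = cfg or NnFilterConfig()
    in_bounds = rr.intervals[(rr.intervals >= cfg.min_ms)
                             & (rr.intervals <= cfg.max_ms)]
    # Seed the reference from the bulk of the early record so that an
    # ectopic first beat cannot lock the running median onto the wrong scale.
    init_med = float(np.median(in_bounds[:11])) if in_bounds.size else None
    accepted: list[float] = []
    removed: list[int] = []
    log: list[tuple[int, float, str]] = []
    for k, value in enumerate(rr.intervals):
        if not (cfg.min_ms <= value <= cfg.max_ms):
            removed.append(k)
            log.append((k, float(value), "outside physiological range"))
            continue
        if len(accepted) >= cfg.median_window:
            med = float(np.median(accepted[-cfg.median_window:]))
        else:
            med = init_med
        if med is not None and abs(value - med) > cfg.frac * med:
            removed.append(k)
            log.append((k, float(value),
                        f"deviates >{cfg.frac:.0%} from running median"))
            continue
        accepted.append(float(value))
    if not accepted:
        raise ValidationError("all intervals rejected by the NN filter")
    series = RrSeries.from_intervals(np.asarray(accepted), is_nn=True,
                                     label=f"{rr.label} (NN)".strip())
    return NnFilterResult(series=series,
                          removed_indices=np.asarray(removed, dtype=int),
                          removal_log=log)
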