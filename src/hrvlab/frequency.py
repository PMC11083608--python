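"""Frequency-domain HRV: tachogram resampling, Welch periodogram, band powers.

The irregularly sampled tachogram (interval value against the time the
interval ends) is cubic-spline interpolated onto a uniform 4 Hz grid.  The
power spectral density is then estimated by Welch's method: the mean-removed
series is split into 50%-overlapping segments, each weighted by a Hamming
window w(n), and the modified periodograms — normalized by the window power
U = mean(w^2) — are averaged over the K segments.  The one-sided density is
scaled so that its trapezoidal integral over frequency equals the variance of
the series, putting band powers in ms^2.

Band powers integrate the density over the standard HRV ranges
VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz and HF 0.15-0.4 Hz; normalized units are
lf/(lf+hf) and hf/(lf+hf), and LF/HF is their ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import get_window

from .errors import ValidationError
from .io import RrSeries, register_report

__all__ = [
    "SpectralReport",
    "WelchConfig",
    "resample_tachogram",
    "welch_psd",
    "band_powers",
    "spectral_analysis",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
]

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings: Hamming window, 50% overlap by default.

    ``seg_len`` = 256 samples is 64 s at the 4 Hz resampling rate, giving at
    least four averaged segments on a 5-min record.
    """

    fs_resample: float = 4.0
    seg_len: int = 256
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValidationError("overlap must be in [0, 1)")
        if self.seg_len < 8:
            raise ValidationError("seg_len must be at least 8 samples")
        if self.fs_resample <= 2 * HF_BAND[1]:
            raise ValidationError(
                f"fs_resample must exceed {2 * HF_BAND[1]} Hz (Nyquist for HF)"
            )


@register_report
@dataclass
class SpectralReport:
    """Welch spectral result: density in ms^2/Hz, band powers in ms^2."""

    freqs: np.ndarray
    psd: np.ndarray
    vlf_power: float
    lf_power: float
    hf_power: float
    lf_nu: float | None
    hf_nu: float | None
    lf_hf: float | None
    settings: dict = field(default_factory=dict)


def resample_tachogram(rr: RrSeries, fs_resample: float = 4.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resample the tachogram onto a uniform grid.

    Returns ``(times_s, values_ms)``.  The grid spans [first, last] interval
    time at spacing ``1/fs_resample``; no extrapolation is performed.
    """
    if rr.n_intervals < 4:
        raise ValidationError("need at least 4 beats to resample")
    if rr.duration < 10:
        raise ValidationError("record shorter than 10 s")
    if rr.duration < 60:
        warnings.warn("tachogram shorter than 60 s; spectral estimates will "
                      "be unreliable", stacklevel=2)
    t = rr.interval_times
    spline = CubicSpline(t, rr.intervals)
    n = int(np.floor((t[-1] - t[0]) * fs_resample)) + 1
    grid = t[0] + np.arange(n) / fs_resample
    return grid, spline(grid)


def welch_psd(x: np.ndarray, cfg: WelchConfig | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of a uniform series; returns one-sided ``(freqs, psd)``.

    The mean is removed first (no further detrending, so the VLF band is
    preserved); the estimate integrates to the series variance.
    """
    cfg = cfg or WelchConfig()
    x = np.asarray(x, dtype=float)
    m = int(cfg.seg_len)
    if x.size < m:
        raise ValidationError(f"series ({x.size}) shorter than seg_len ({m})")
    fs = cfg.fs_resample
    x = x - x.mean()
    step = max(1, int(round(m * (1 - cfg.overlap))))
    starts = np.arange(0, x.size - m + 1, step)
    # Periodic (DFT-even) Hamming window, the spectral-estimation convention.
    w = get_window("hamming", m, fftbins=True)
    u = float(np.mean(w**2))
    # Modified periodogram per segment, averaged over the K segments.
    acc = np.zeros(m // 2 + 1)
    for s in starts:
        seg = x[s:s + m] * w
        spec = np.abs(np.fft.rfft(seg)) ** 2
        acc += spec
    pxx = acc / (starts.size * m * u)
    # One-sided physical scaling: density in (units^2)/Hz.
    pxx = pxx / fs
    pxx[1:-1] *= 2.0
    if m % 2 == 1:
        pxx[-1] *= 2.0
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    return freqs, pxx


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                vlf: tuple[float, float] = VLF_BAND,
                lf: tuple[float, float] = LF_BAND,
                hf: tuple[float, float] = HF_BAND,
                settings: dict | None = None) -> SpectralReport:
    """Integrate the density over the VLF/LF/HF bands and derive n.u. and LF/HF."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size != psd.size or freqs.size < 4:
        raise ValidationError("freqs and psd must be equal-length (>= 4)")
    if (np.diff(freqs) <= 0).any():
        raise ValidationError("freqs must be strictly increasing")
    if freqs[-1] < hf[1]:
        raise ValidationError(
            f"frequency grid tops out at {freqs[-1]:g} Hz; must cover {hf[1]} Hz"
        )
    powers = [_trapz_band(freqs, psd, lo, hi) for lo, hi in (vlf, lf, hf)]
    vlf_p, lf_p, hf_p = powers
    if lf_p + hf_p > 0:
        lf_nu = lf_p / (lf_p + hf_p)
        hf_nu = hf_p / (lf_p + hf_p)
    else:
        lf_nu = hf_nu = None
    if hf_p > 0:
        lf_hf = lf_p / hf_p
    else:
        lf_hf = None
        warnings.warn("HF power is zero; LF/HF undefined", stacklevel=2)
    return SpectralReport(
        freqs=freqs, psd=psd, vlf_power=vlf_p, lf_power=lf_p, hf_power=hf_p,
        lf_nu=lf_nu, hf_nu=hf_nu, lf_hf=lf_hf, settings=settings or {},
    )


def _trapz_band(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi), with edge interpolation."""
    grid = [lo] + [float(f) for f in freqs if lo < f < hi] + [hi]
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def spectral_analysis(rr: RrSeries, cfg: WelchConfig | None = None
                      ) -> SpectralReport:
    """Full pipeline: resample -> Welch -> band powers."""
    cfg = cfg or WelchConfig()
    _, values = resample_tachogram(rr, cfg.fs_resample)
    freqs, psd = welch_psd(values, cfg)
    return band_powers(freqs, psd, settings={
        "fs_resample": cfg.fs_resample, "seg_len": cfg.seg_len,
        "overlap": cfg.overlap, "window": "hamming",
    })
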