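"""ECG conditioning ahead of QRS detection.

The chain applies, in order: moving-average smoothing, DC removal,
median-filter baseline estimation (subtracted), and a zero-phase low-pass.
All stages are zero-phase (centered windows, forward-backward IIR) so that
R-peak fiducial timing is preserved — HRV accuracy hinges on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import ValidationError
from .io import EcgRecord

__all__ = ["PreprocessConfig", "preprocess_ecg"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter-chain parameters.

    ``w_avg_samples``: moving-average width (samples, odd for zero phase).
    ``w_med_seconds``: median-filter baseline window (s) — longer than any
    QRS complex, shorter than the baseline-wander period.
    ``f_lp_hz`` / ``lp_order``: zero-phase Butterworth low-pass cutoff/order.
    Any stage can be disabled by setting its parameter to 0/None.
    """

    w_avg_samples: int = 5
    w_med_seconds: float = 0.6
    f_lp_hz: float = 40.0
    lp_order: int = 4

    def __post_init__(self) -> None:
        if self.w_avg_samples < 0:
            raise ValidationError("w_avg_samples must be >= 0")
        if self.w_med_seconds < 0:
            raise ValidationError("w_med_seconds must be >= 0")
        if self.f_lp_hz < 0:
            raise ValidationError("f_lp_hz must be >= 0")


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average (zero phase for odd widths); width<=1 is identity."""
    if width <= 1:
        return x.copy()
    return ndimage.uniform_filter1d(x, size=width, mode="nearest")


def remove_dc(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def median_baseline(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Baseline estimate via a centered median filter of ``window_s`` seconds."""
    kernel = int(round(window_s * fs))
    kernel += 1 - kernel % 2  # odd
    if kernel <= 1:
        return np.zeros_like(x)
    return signal.medfilt(x, kernel_size=kernel)


def lowpass_zero_phase(x: np.ndarray, fs: float, cutoff: float, order: int
                       ) -> np.ndarray:
    if cutoff <= 0 or cutoff >= fs / 2:
        return x.copy()
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def preprocess_ecg(ecg: EcgRecord, cfg: PreprocessConfig | None = None) -> EcgRecord:
    """Run the four-stage denoising chain; output keeps length, fs and t0."""
    cfg = cfg or PreprocessConfig()
    n = ecg.n_samples
    if cfg.w_med_seconds * ecg.fs >= n:
        raise ValidationError(
            f"median window ({cfg.w_med_seconds} s) is not shorter than the "
            f"record ({ecg.duration:g} s)"
        )
    if cfg.w_avg_samples >= n:
        raise ValidationError("moving-average window longer than the record")
    x = moving_average(ecg.samples, cfg.w_avg_samples)
    x = remove_dc(x)
    x = x - median_baseline(x, ecg.fs, cfg.w_med_seconds)
    x = lowpass_zero_phase(x, ecg.fs, cfg.f_lp_hz, cfg.lp_order)
    return EcgRecord(samples=x, fs=ecg.fs, t0=ecg.t0,
                     label=f"{ecg.label} (preprocessed)".strip())
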