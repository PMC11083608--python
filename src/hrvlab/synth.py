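"""Synthetic cardiac signal generation: RR tachograms and template-based ECG.

The RR generator is the package's ground-truth source.  Each beat-to-beat
interval is drawn sequentially as

    RR(t) = mean_rr(t) + rsa_amp * sin(2*pi*rsa_freq*t)
                       + lf_amp  * sin(2*pi*lf_freq*t + phi)
                       + vlf_amp * sin(2*pi*vlf_freq*t + psi)
                       + Gaussian(0, noise_sd)

where ``t`` is the current beat time and ``mean_rr(t)`` is piecewise constant
(``regime_shifts`` move it).  The three sinusoidal modulations emulate
respiratory sinus arrhythmia (HF band), baroreflex/Mayer waves (LF band) and
slow thermoregulatory drift (VLF band).  Extrasystoles are modeled as a
premature beat (interval scaled by ``ectopy_prematurity``) followed by a
compensatory pause (next interval multiplied by ``compensatory_pause``), the
classic bigeminy-like signature of ventricular/supraventricular ectopy.

Three shipped cohort presets mirror the phenomenology of the study groups:

* ``healthy`` — mean RR at the healthy-group scale (~892 ms), strong
  modulation in all three bands, clearly visible beat-to-beat variability.
* ``arrhythmia`` — sinus base with low beat-to-beat variability plus
  frequent extrasystoles with compensatory pauses.
* ``syncope`` — very low short-term variability with multi-regime mean
  shifts ("torpedo"/segmented Poincare cloud).

ECG synthesis places a parameterized P-QRS-T template at each beat time and
returns the exact R-peak sample indices, giving the QRS detector a known
truth to be scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .io import EcgRecord, RrSeries

__all__ = [
    "CohortSpec",
    "EcgSynthSpec",
    "generate_rr",
    "generate_ecg",
    "default_cohort_spec",
    "COHORTS",
]

BEAT_NORMAL = "normal"
BEAT_ECTOPIC = "ectopic"
BEAT_PAUSE = "pause"

# Band limits (Hz) that the modulation frequencies must respect.
HF_BAND = (0.15, 0.4)
LF_BAND = (0.04, 0.15)
VLF_BAND = (0.003, 0.04)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Amplitudes and sds are in ms, frequencies in Hz.  ``regime_shifts`` is a
    list of ``(time_s, new_mean_rr_ms)`` pairs applied in order.
    """

    cohort: str = "healthy"
    mean_rr: float = 892.0
    rsa_amp: float = 0.0
    rsa_freq: float = 0.25
    lf_amp: float = 0.0
    lf_freq: float = 0.1
    vlf_amp: float = 0.0
    vlf_freq: float = 0.02
    ectopy_rate: float = 0.0
    ectopy_prematurity: float = 0.6
    compensatory_pause: float = 1.4
    regime_shifts: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mean_rr > 0):
            raise ValidationError("mean_rr must be > 0")
        if not (0 <= self.ectopy_rate < 1):
            raise ValidationError("ectopy_rate must be in [0, 1)")
        if not (0 < self.ectopy_prematurity < 1):
            raise ValidationError("ectopy_prematurity must be in (0, 1)")
        if self.ectopy_rate > 0 and not (self.compensatory_pause > 1):
            raise ValidationError("compensatory_pause must be > 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name, freq, band in (
            ("rsa_freq", self.rsa_freq, HF_BAND),
            ("lf_freq", self.lf_freq, LF_BAND),
            ("vlf_freq", self.vlf_freq, VLF_BAND),
        ):
            if not (band[0] < freq < band[1]):
                raise ValidationError(
                    f"{name}={freq} Hz outside its band ({band[0]}, {band[1]})"
                )

    def expected_rmssd(self) -> float:
        """Analytic RMSSD of the generator for a shift-free, ectopy-free spec.

        Successive differences of a sinusoid of amplitude ``a`` sampled every
        ``dt = mean_rr/1000`` s have mean square ``2 a^2 sin^2(pi f dt)``;
        white noise contributes ``2 noise_sd^2``.
        """
        dt = self.mean_rr / 1000.0
        msd = 2.0 * self.noise_sd**2
        for amp, freq in (
            (self.rsa_amp, self.rsa_freq),
            (self.lf_amp, self.lf_freq),
            (self.vlf_amp, self.vlf_freq),
        ):
            msd += 2.0 * amp**2 * np.sin(np.pi * freq * dt) ** 2
        return float(np.sqrt(msd))


_DEFAULT_SPECS: dict[str, CohortSpec] = {
    # Mean RRs sit at the study-group scales (~892 / 746 / 654 ms).
    "healthy": CohortSpec(
        cohort="healthy", mean_rr=892.0,
        rsa_amp=25.0, rsa_freq=0.25,
        lf_amp=30.0, lf_freq=0.1,
        vlf_amp=40.0, vlf_freq=0.02,
        noise_sd=10.0,
    ),
    "arrhythmia": CohortSpec(
        cohort="arrhythmia", mean_rr=746.0,
        rsa_amp=2.0, rsa_freq=0.25,
        lf_amp=4.0, lf_freq=0.1,
        vlf_amp=8.0, vlf_freq=0.02,
        ectopy_rate=0.08, ectopy_prematurity=0.6, compensatory_pause=1.4,
        noise_sd=2.0,
    ),
    "syncope": CohortSpec(
        cohort="syncope", mean_rr=654.0,
        rsa_amp=1.0, rsa_freq=0.25,
        lf_amp=2.0, lf_freq=0.1,
        vlf_amp=3.0, vlf_freq=0.02,
        regime_shifts=((300.0, 720.0), (600.0, 600.0), (900.0, 680.0)),
        noise_sd=1.5,
    ),
}

COHORTS = tuple(_DEFAULT_SPECS)


def default_cohort_spec(cohort: str, seed: int = 0) -> CohortSpec:
    """Shipped preset for ``cohort`` in {healthy, arrhythmia, syncope}."""
    try:
        spec = _DEFAULT_SPECS[cohort]
    except KeyError:
        raise ValidationError(
            f"unknown cohort {cohort!r}; choose from {sorted(_DEFAULT_SPECS)}"
        ) from None
    return replace(spec, seed=seed)


_MIN_RR_MS = 150.0  # physiological hard floor so intervals stay positive


def generate_rr(spec: CohortSpec, duration: float) -> tuple[RrSeries, np.ndarray]:
    """Generate a seeded RR tachogram of at least ``duration`` seconds.

    Returns the series and a per-interval truth label array with values
    ``"normal"``, ``"ectopic"`` (premature beat) or ``"pause"``
    (post-extrasystolic compensatory pause).  Identical spec (including seed)
    yields identical output.
    """
    if duration < 60:
        raise ValidationError("duration must be at least 60 s")
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(0, 2 * np.pi)
    psi = rng.uniform(0, 2 * np.pi)

    shifts = sorted(spec.regime_shifts, key=lambda p: p[0])
    intervals: list[float] = []
    labels: list[str] = []
    t = 0.0
    mean_rr = spec.mean_rr
    shift_idx = 0
    pause_next = False
    while t < duration:
        while shift_idx < len(shifts) and t >= shifts[shift_idx][0]:
            mean_rr = float(shifts[shift_idx][1])
            shift_idx += 1
        rr = (
            mean_rr
            + spec.rsa_amp * np.sin(2 * np.pi * spec.rsa_freq * t)
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t + phi)
            + spec.vlf_amp * np.sin(2 * np.pi * spec.vlf_freq * t + psi)
            + rng.normal(0.0, spec.noise_sd)
        )
        if pause_next:
            rr *= spec.compensatory_pause
            label = BEAT_PAUSE
            pause_next = False
        elif spec.ectopy_rate > 0 and rng.random() < spec.ectopy_rate:
            rr *= spec.ectopy_prematurity
            label = BEAT_ECTOPIC
            pause_next = True
        else:
            label = BEAT_NORMAL
        rr = max(rr, _MIN_RR_MS)
        intervals.append(rr)
        labels.append(label)
        t += rr / 1000.0
    series = RrSeries.from_intervals(
        np.asarray(intervals), is_nn=False, label=f"synthetic-{spec.cohort}"
    )
    return series, np.asarray(labels)


@dataclass(frozen=True)
class EcgSynthSpec:
    """Template-based ECG synthesis parameters.

    The beat template is a sum of Gaussians (P, Q, R, S, T waves); amplitudes
    in mV, centers/widths in ms relative to the R peak.
    """

    fs: float = 250.0
    p_amp: float = 0.15
    p_center: float = -180.0
    p_width: float = 25.0
    q_amp: float = -0.15
    q_center: float = -25.0
    q_width: float = 8.0
    r_amp: float = 1.5
    r_width: float = 10.0
    s_amp: float = -0.25
    s_center: float = 25.0
    s_width: float = 8.0
    t_amp: float = 0.3
    t_center: float = 220.0
    t_width: float = 60.0
    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.3
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    white_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValidationError("fs must be at least 100 Hz")
        if self.r_amp <= 0:
            raise ValidationError("r_amp must be > 0")

    @property
    def qrs_halfwidth_ms(self) -> float:
        """Half-width (ms) of the QRS portion of the template."""
        return max(abs(self.q_center) + 3 * self.q_width,
                   abs(self.s_center) + 3 * self.s_width,
                   4 * self.r_width)


def _beat_template(spec: EcgSynthSpec, t_ms: np.ndarray) -> np.ndarray:
    """Evaluate the P-QRS-T template at times ``t_ms`` relative to the R peak."""
    out = np.zeros_like(t_ms)
    for amp, center, width in (
        (spec.p_amp, spec.p_center, spec.p_width),
        (spec.q_amp, spec.q_center, spec.q_width),
        (spec.r_amp, 0.0, spec.r_width),
        (spec.s_amp, spec.s_center, spec.s_width),
        (spec.t_amp, spec.t_center, spec.t_width),
    ):
        out += amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return out


def generate_ecg(rr: RrSeries, spec: EcgSynthSpec) -> tuple[EcgRecord, np.ndarray]:
    """Synthesize an ECG with one template beat per beat time of ``rr``.

    Returns the record and the exact truth R-peak sample indices.  Beats are
    placed at ``rr.beat_times`` shifted by a fixed 0.5 s lead-in so the first
    template is not clipped; additive baseline wander, powerline interference
    and white noise follow the spec.
    """
    if rr.intervals.min() <= 2 * spec.qrs_halfwidth_ms:
        raise ValidationError(
            "QRS template wider than the shortest RR interval "
            f"({rr.intervals.min():g} ms)"
        )
    lead_in = 0.5
    tail = 0.8
    fs = spec.fs
    peak_times = lead_in + (rr.beat_times - rr.beat_times[0])
    n = int(np.ceil((peak_times[-1] + tail) * fs)) + 1
    t = np.arange(n) / fs
    signal = np.zeros(n)
    # Snap each R peak to the nearest sample so truth indices are exact.
    peak_indices = np.rint(peak_times * fs).astype(int)
    window_ms = max(350.0, spec.t_center + 4 * spec.t_width,
                    abs(spec.p_center) + 4 * spec.p_width)
    half = int(np.ceil(window_ms / 1000.0 * fs))
    for idx in peak_indices:
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        rel_ms = (np.arange(lo, hi) - idx) / fs * 1000.0
        signal[lo:hi] += _beat_template(spec, rel_ms)
    rng = np.random.default_rng(spec.seed)
    if spec.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += spec.baseline_wander_amp * np.sin(
            2 * np.pi * spec.baseline_wander_freq * t + phase
        )
    if spec.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += spec.powerline_amp * np.sin(
            2 * np.pi * spec.powerline_freq * t + phase
        )
    if spec.white_noise_sd > 0:
        signal += rng.normal(0.0, spec.white_noise_sd, size=n)
    record = EcgRecord(samples=signal, fs=fs, t0=0.0,
                       label=f"synthetic-ecg ({rr.label})")
    return record, peak_indices
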