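# Methods

This note documents the models, defaults and numerical choices behind
hrvlab, and what the synthetic validation does and does not demonstrate.

## Signal model and conventions

An RR series with `n` intervals carries `n + 1` beat times (seconds from
record start); `beat_times[k+1] − beat_times[k] = intervals[k]/1000` holds
to 1e−9 s. Intervals are ms everywhere. The tachogram abscissa is the time
at which each interval *ends*. After NN filtering the series is re-timed by
the cumulative sum of accepted intervals so segmentation and spline
resampling see a contiguous record; this shortens the time axis by the
removed intervals, which is the conventional trade-off for spectral
analysis of gap-filtered tachograms.

## Synthetic cohort generator

The generator is the package's source of ground truth. Beat-to-beat
intervals are drawn sequentially as a piecewise-constant mean plus three
sinusoidal modulations — respiratory sinus arrhythmia in the HF band
(default 0.25 Hz), a baroreflex/Mayer-wave component in LF (0.1 Hz) and a
slow drift in VLF (0.02 Hz) — plus white Gaussian noise. Extrasystoles are
premature beats (interval × `ectopy_prematurity`, default 0.6) followed by
a compensatory pause (next interval × `compensatory_pause`, default 1.4),
each beat labeled so NN-filter tests have truth. All randomness (modulation
phases, noise, ectopy draws) flows from one integer seed; identical spec ⇒
identical series.

Shipped presets (chosen once, from the phenomenology of the three studied
conditions, at the groups' mean-RR scales):

| preset | mean RR | RSA/LF/VLF amp (ms) | noise sd | ectopy | regime shifts |
|---|---|---|---|---|---|
| healthy | 892 ms | 25 / 30 / 40 | 10 | – | – |
| arrhythmia | 746 ms | 2 / 4 / 8 | 2 | 8 % of beats | – |
| syncope | 654 ms | 1 / 2 / 3 | 1.5 | – | 720/600/680 ms at 300/600/900 s |

The closed-form RMSSD of a shift-free spec is
`sqrt(Σ 2a² sin²(π f ΔT) + 2σ²)` with `ΔT = mean_rr/1000`; the Monte-Carlo
mean over 50 seeds agrees within 0.2 % at ≥ 2000 beats, which is the
parameter-recovery check in the tests.

What the generator does **not** emulate: morphology differences between
ventricular and supraventricular ectopy, circadian nonstationarity,
respiration–heart-rate coupling beyond a fixed-frequency sinusoid, and
measurement artifacts other than additive noise. Passing tests therefore
demonstrate correctness of the *analysis* operators and the direction of
cohort effects under this model — not clinical performance.

The ECG synthesizer places a Gaussian P-QRS-T template at each beat time
(R amplitude 1.5 mV, QRS half-width ≈ 50 ms) with optional baseline wander,
powerline interference and white noise; truth R-peak indices are exact by
construction, enabling ±1-sample detector scoring.

## Preprocessing

Four stages, in order: centered moving average (5 samples), DC removal,
median-filter baseline estimation (0.6 s window — longer than any QRS,
shorter than the wander period) subtracted from the signal, and a 4th-order
zero-phase Butterworth low-pass at 40 Hz. Every stage is zero-phase so the
chain shifts R-peak timing by at most one sample on noise-free signals
(verified in tests). All parameters are configurable.

## QRS detection

Classic Pan–Tompkins constants: band-pass 5–15 Hz (2nd-order Butterworth,
forward–backward), five-point derivative applied centered, squaring, 150 ms
moving-window integration, adaptive signal/noise thresholds with update
coefficient 0.125 and threshold fraction 0.25, 200 ms refractory period,
360 ms T-wave discrimination by comparing maximal band-passed slopes, and
search-back at half threshold when no beat arrives within 1.66× the running
RR average (last 8 intervals). Thresholds are learned from the first two
seconds. The R peak is localized as the raw-signal maximum within ±100 ms
of each accepted integrator peak; sub-sample parabolic refinement is
available but off by default (beat times are sample/fs).

The NN filter accepts an interval when it is inside [300, 2000] ms and
within 20 % of the median of the previous five accepted intervals. The
reference median is initialized from the median of the first eleven
in-bounds intervals, so a recording that *begins* with an ectopic beat
cannot capture the filter (without this, a premature first beat locks the
running median onto the wrong scale and the filter inverts). The filter is
idempotent and achieves 100 % recall of labeled ectopics/pauses on the
arrhythmia preset at ~1000 beats.

## Time-domain and geometric indices

SDNN is the sample (n−1) standard deviation of all NN intervals of the
record; SDANN the sample sd of 5-minute segment means; SDNN Index the mean
of 5-minute segment sds (both `null` below two complete segments,
incomplete tails dropped); RMSSD the root mean square of successive
differences; pNN50 uses the number of successive differences (n−1) as
denominator and is reported in percent. The histogram uses 7.8125 ms
(1/128 s) bins aligned to zero. HRVTi = total count / modal count. TINN is
found by brute-force least squares over triangles with apex at the mode
center and base endpoints on a half-bin-width grid (edges *and* centers,
extended two bins beyond the range): an exactly triangular histogram has
its zero crossings half a bin beyond the outermost centers, so edge-only
candidates would bias the base by up to two bins.

## Spectral analysis

The tachogram is cubic-spline interpolated onto a uniform 4 Hz grid
spanning the record (no extrapolation). Welch segments are 256 samples
(64 s) with 50 % overlap — at least four segments on a 5-minute record —
weighted by a *periodic* Hamming window (the DFT-even spectral-estimation
convention; the test suite verifies exact agreement with an independent
Welch implementation). Each segment's periodogram is normalized by the
window power U = mean(w²), averaged over segments, and scaled to a
one-sided density whose trapezoidal integral equals the series variance, so
band powers are in ms². Only the mean is removed (no polynomial detrend):
the VLF band is reported and aggressive detrending would corrupt it. Band
powers integrate the density over VLF/LF/HF with linear interpolation at
band edges; normalized units are LF/(LF+HF) and HF/(LF+HF).

## Poincaré quantification

SD1/SD2 are population (1/n) standard deviations of the rotated
coordinates (y−x)/√2 and (y+x)/√2 of the lag-1 point cloud, making
SD1 = RMSSD/√2 exact whenever the mean successive difference is zero and
SD1² + SD2² equal to the total coordinate variance (rotation invariance) —
both asserted in tests. This deliberately differs from the sample-sd
convention used for SDNN. Standard deviations below 1e−12 of the signal
scale are clamped to zero (pairwise-summation residue on constant input);
SD1/SD2 is `null` when SD2 = 0. A lag-m generalization is exposed
(default 1).

## Recurrence analysis

States are delay embeddings of the NN series; the recurrence threshold
defaults to 0.1× the maximum pairwise distance of the embedded cloud
(fixed-ε variant exposed; Euclidean or maximum norm). The line of identity
is excluded from every count. REC is the recurrent fraction of the N²−N
off-identity cells. DET/LAM are the fractions of recurrent points on
diagonal/vertical runs of length ≥ 2 (the matrix is symmetric, so vertical
and horizontal counts coincide); ENTR is the Shannon entropy, in nats, of
the diagonal-length distribution at lengths ≥ 2. Histograms count both
matrix triangles. Note that a completely recurrent matrix yields
DET = LAM = 100·(N²−3N+2)/(N²−N) %, not exactly 100 %: the two single-cell
corner diagonals can never reach the minimum line length. Implementation
agreement with a naive double-loop oracle — full histograms, not just
percentages — is asserted on random inputs. When the embedding is not
given, delay and dimension are derived per record from AMI/FNN.

## Phase-space diagnostics

AMI is estimated from a 2-D equal-width histogram in nats. The default
partition is deliberately coarse (4 bins per axis): finer partitions
resolve more structure but, on strongly periodic signals, develop
bin-resonance wiggles — shallow spurious minima superimposed on the true
AMI valley. For the same reason the delay is chosen at the first local
minimum with prominence ≥ 0.1× the curve's range (falling back to the
global minimum, with a warning, when no prominent minimum exists, e.g. for
white noise). With these defaults the estimator recovers the quarter-period
delay of a sinusoid exactly, across phases, periods and record lengths. Bin
count, prominence and an equiprobable-bin variant are configurable.

FNN uses the standard Kennel criteria (ratio threshold 15, absolute
threshold 2× series sd, Theiler exclusion = delay); the embedding dimension
is the first with ≤ 1 % false neighbors. Neighbor distances below 1e−9×
the series sd are treated as duplicates: the next-nearest distinct
neighbor is used instead, and if none exists the absolute criterion alone
decides (at float precision, "exact" duplicates of periodic signals carry
round-off distances that would otherwise trigger the ratio test
spuriously). FNN curves may be non-monotone and are reported as-is.

## Statistics

Welch (unequal-variance) two-sided t-tests compare the reference cohort
against each other cohort; the equal-variance variant is behind a flag.
One-way ANOVA spans all cohorts. No multiple-testing correction is applied
by default. The MSE between two equal-length series is (1/N)Σ(xᵢ−yᵢ)²; the
relative error compares series means in percent — appropriate for
device-against-device comparisons of beat counts and mean intervals, where
no per-beat pairing rule exists.

## Problem sizes used in validation

The test suite and acceptance script use synthetic records of 120–600 s
(detector checks: 120 s per heart rate at fs = 250 Hz; cohort
discrimination: 600 s per seed, 50 seeds; analytic-RMSSD recovery: ≥ 2000
beats), 1000 null simulations for ANOVA calibration, and series of length
≤ 200 for exact RQA-oracle comparison. These sizes were chosen so every
statistical check is comfortably powered while the whole suite remains
quick to run on one core.

## Known limitations

* The cohort presets are stand-ins with the right direction and rough scale
  of group effects; they are not fitted to clinical data, and no clinical
  claim follows from the tests.
* The NN filter's median-of-five/20 % rule is one standard choice among
  several; its thresholds are exposed precisely because no single rule
  suits all pathologies.
* ENTR depends on the embedding and threshold conventions above; absolute
  values are comparable only under identical settings.
* WFDB and other binary Holter formats are out of scope; ECG I/O is plain
  CSV (one voltage per line, or time,voltage rows checked against the
  stated sampling rate within 1 %).
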