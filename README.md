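# hrvlab

Heart-rate-variability (HRV) analysis from raw single-lead ECG or RR-interval
tachograms, for researchers in cardiac electrophysiology and biomedical
signal processing who need a reproducible, fully tested pipeline from raw
signal to report.

The package covers the standard HRV workflow end to end:

* **Preprocessing** — moving-average smoothing, DC removal, median-filter
  baseline subtraction and a zero-phase low-pass, so R-peak timing is
  preserved.
* **QRS detection** — the Pan–Tompkins algorithm (band-pass 5–15 Hz,
  five-point derivative, squaring, 150 ms moving-window integration,
  adaptive dual thresholds with 200 ms refractory period, 360 ms T-wave
  discrimination and search-back), followed by RR-interval construction and
  a median-of-five normal-to-normal (NN) filter with ground-truth-auditable
  removal logs.
* **Time-domain indices** — MeanRR, SDNN, SDANN, RMSSD, SDNN Index, pNN50,
  plus the geometric pair HRVTi = N / max(histogram) and TINN (base of the
  least-squares triangle fitted to the NN histogram, 7.8125 ms bins).
* **Frequency domain** — cubic-spline resampling of the tachogram at 4 Hz,
  Welch periodogram (Hamming window, 50 % overlap, window-power
  normalization U = mean(w²)), band powers over VLF 0.003–0.04 Hz,
  LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, normalized units LF/(LF+HF), HF/(LF+HF)
  and the LF/HF ratio.
* **Nonlinear methods** — Poincaré SD1/SD2 (population-normalized, so
  SD1 = RMSSD/√2 for balanced successive differences), recurrence
  quantification (REC, DET, LAM, ENTR with full line-length histograms),
  and phase-space diagnostics (delay from the first prominent minimum of
  the average mutual information, dimension from false nearest neighbors,
  3-D attractor export).
* **Statistics** — MSE and relative-error device-validation measures, Welch
  t-tests and one-way ANOVA cohort comparisons, and a pipeline that
  aggregates every index per cohort into a publication-style table.
* **Synthetic cohorts** — a seeded generator producing RR series (and
  template-based ECG with exact R-peak ground truth) for three cohort
  presets: `healthy`, `arrhythmia` (extrasystoles with compensatory
  pauses) and `syncope` (very low short-term variability with regime
  shifts), so every stage is testable without clinical recordings.

## Worked example

```bash
# 1. Generate a 10-minute synthetic healthy recording (RR + ECG + truth)
hrvlab synth --cohort healthy --duration 600 --ecg --seed 42 --out demo

# 2. Detect QRS complexes in the ECG and build the NN series
hrvlab detect demo/healthy-000.ecg.csv --fs 250 --out demo

# 3. Full analysis of the tachogram
hrvlab analyze demo/healthy-000.ecg.rr.txt --seed 42 --out demo/reports
python -c "import json;d=json.load(open('demo/reports/time.json'))['data'];\
print({k: round(v,2) for k,v in d.items() if isinstance(v,(int,float))})"
```

The last step prints (run as above):

```
{'hrv_ti': 11.23, 'mean_rr': 890.65, 'n_intervals': 674, 'pnn50': 9.81,
 'rmssd': 29.93, 'sdann': 0.49, 'sdnn': 40.54, 'sdnn_index': 40.59,
 'segment_count': 2, 'tinn': 179.69}
```

Read: the mean interbeat interval is ~891 ms (~67 bpm); overall variability
SDNN ≈ 41 ms and short-term (vagal) variability RMSSD ≈ 30 ms are in the
healthy range; the 10-minute record yields two complete 5-minute segments,
so SDANN (variability *between* segment means, tiny for a stationary
recording) and SDNN Index (mean within-segment variability) are defined.
`demo/reports/` also contains
`frequency.json` (band powers in ms², n.u., LF/HF), `poincare.json`
(SD1/SD2), `rqa.json` (REC/DET/LAM/ENTR), `embedding.json` (AMI/FNN
curves), and plot-ready CSVs (tachogram, histogram, PSD, Poincaré points,
attractor).

The same operations are available as library functions:

```python
from hrvlab import generate_rr, default_cohort_spec, time_domain, poincare

rr, truth = generate_rr(default_cohort_spec("healthy", seed=42), 600)
rr.is_nn = True
print(time_domain(rr).rmssd, poincare(rr).sd1)
```

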