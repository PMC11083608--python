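"""Shared fixtures: deterministic synthetic series and scoring helpers."""

import numpy as np
import pytest

from hrvlab import RrSeries, default_cohort_spec, generate_rr


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def constant_rr():
    return RrSeries.from_intervals(np.full(200, 800.0), is_nn=True)


@pytest.fixture()
def healthy_rr():
    """10-minute healthy-cohort NN tachogram, fixed seed."""
    rr, _ = generate_rr(default_cohort_spec("healthy", seed=7), 600)
    return RrSeries(rr.intervals, rr.beat_times, is_nn=True)


def match_peaks(truth, detected, tol_samples):
    """Greedy one-to-one peak matching; returns (tp, fp, fn)."""
    truth = np.asarray(truth)
    detected = np.asarray(detected)
    used = set()
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        j = int(np.argmin(np.abs(detected - t)))
        if abs(int(detected[j]) - int(t)) <= tol_samples and j not in used:
            tp += 1
            used.add(j)
    return tp, detected.size - tp, truth.size - tp
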