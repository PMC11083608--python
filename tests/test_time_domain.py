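"""Time-domain indices against direct-formula and brute-force oracles."""

import numpy as np
import pytest

from hrvlab import (
    RrSeries,
    ValidationError,
    geometric_indices,
    rr_histogram,
    time_domain,
)
from hrvlab.time_domain import DEFAULT_BIN_WIDTH_MS, RrHistogram


def oracle_time_domain(intervals, beat_times, segment_seconds=300.0):
    """Direct-formula reference, written independently of the implementation."""
    x = np.asarray(intervals, dtype=float)
    d = x[1:] - x[:-1]
    out = {
        "mean_rr": x.sum() / x.size,
        "sdnn": np.sqrt(((x - x.mean()) ** 2).sum() / (x.size - 1)),
        "rmssd": np.sqrt((d**2).sum() / d.size),
        "pnn50": 100.0 * (np.abs(d) > 50).sum() / d.size,
    }
    t_end = beat_times[1:] - beat_times[0]
    total = beat_times[-1] - beat_times[0]
    n_seg = int(total // segment_seconds)
    means, sds = [], []
    for k in range(n_seg):
        seg = x[(t_end > k * segment_seconds)
                & (t_end <= (k + 1) * segment_seconds)]
        if seg.size >= 2:
            means.append(seg.mean())
            sds.append(seg.std(ddof=1))
    if n_seg >= 2 and len(means) >= 2:
        out["sdann"] = float(np.std(means, ddof=1))
        out["sdnn_index"] = float(np.mean(sds))
    else:
        out["sdann"] = out["sdnn_index"] = None
    return out


def random_nn_series(rng, n=None, long=False):
    n = n or int(rng.integers(20, 200))
    if long:
        intervals = rng.uniform(600, 1200, 3000)
    else:
        intervals = rng.uniform(400, 1500, n)
    return RrSeries.from_intervals(intervals, is_nn=True)


class TestTimeDomain:
    def test_constant_series_all_zero_dispersion(self, constant_rr):
        rep = time_domain(constant_rr)
        assert rep.sdnn == 0 and rep.rmssd == 0 and rep.pnn50 == 0
        assert rep.mean_rr == 800.0

    def test_hand_computed_rmssd(self):
        rr = RrSeries.from_intervals(np.array([800.0, 810, 800, 810]),
                                     is_nn=True)
        rep = time_domain(rr)
        assert rep.rmssd == pytest.approx(10.0, abs=1e-12)
        assert rep.pnn50 == 0.0

    def test_forty_minute_series_has_eight_segments(self):
        rr = RrSeries.from_intervals(np.full(2400, 1000.0), is_nn=True)
        rep = time_domain(rr)
        assert rep.segment_count == 8

    def test_matches_direct_formula_oracle(self, rng):
        # 25 random series, including long ones exercising segmentation.
        for case in range(25):
            rr = random_nn_series(rng, long=case % 5 == 0)
            rep = time_domain(rr)
            ref = oracle_time_domain(rr.intervals, rr.beat_times)
            for key, value in ref.items():
                got = getattr(rep, key)
                if value is None:
                    assert got is None
                else:
                    assert got == pytest.approx(value, rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            time_domain(RrSeries.from_intervals(np.array([800.0]), is_nn=True))

    def test_unfiltered_series_warns(self):
        rr = RrSeries.from_intervals(np.full(10, 800.0), is_nn=False)
        with pytest.warns(UserWarning, match="non-NN"):
            time_domain(rr)

    def test_scaling_covariance(self, rng):
        rr = random_nn_series(rng, n=150)
        scaled = RrSeries.from_intervals(1.5 * rr.intervals, is_nn=True)
        a, b = time_domain(rr), time_domain(scaled)
        for name in ("mean_rr", "sdnn", "rmssd"):
            assert getattr(b, name) == pytest.approx(
                1.5 * getattr(a, name), rel=1e-9)
        assert b.hrv_ti >= 1.0 and a.hrv_ti >= 1.0


class TestRrHistogram:
    def test_single_bin_concentration(self):
        rr = RrSeries.from_intervals(np.full(64, 800.0), is_nn=True)
        hist = rr_histogram(rr)
        assert np.count_nonzero(hist.counts) == 1

    def test_counts_conserved(self, rng):
        rr = random_nn_series(rng, n=300)
        hist = rr_histogram(rr)
        assert hist.counts.sum() == rr.n_intervals

    def test_tachycardic_mode_left_of_bradycardic(self, rng):
        tachy = RrSeries.from_intervals(rng.normal(500, 10, 300).clip(min=400),
                                        is_nn=True)
        brady = RrSeries.from_intervals(rng.normal(1100, 10, 300).clip(min=900),
                                        is_nn=True)
        ht, hb = rr_histogram(tachy), rr_histogram(brady)
        assert (ht.bin_edges[ht.mode_bin] < hb.bin_edges[hb.mode_bin])

    def test_invalid_bin_width_rejected(self, constant_rr):
        with pytest.raises(ValidationError):
            rr_histogram(constant_rr, bin_width=0)


def oracle_triangle_fit(counts, edges):
    """Brute-force triangle fit identical in spirit, looped naively."""
    counts = np.asarray(counts, dtype=float)
    mode = int(np.argmax(counts))
    peak = counts[mode]
    centers = (edges[:-1] + edges[1:]) / 2
    apex = centers[mode]
    width = edges[1] - edges[0]
    best_err, best_tinn = np.inf, 0.0
    grid = np.arange(edges[0] - 2 * width, edges[-1] + 2 * width + width / 4,
                     width / 2)
    n_cands = [g for g in grid if g < apex - width / 4]
    m_cands = [g for g in grid if g > apex + width / 4]
    for n_edge in n_cands:
        for m_edge in m_cands:
            err = 0.0
            for c, h in zip(centers, counts):
                if c == apex:
                    tri = peak
                elif n_edge < c < apex:
                    tri = peak * (c - n_edge) / (apex - n_edge)
                elif apex < c < m_edge:
                    tri = peak * (m_edge - c) / (m_edge - apex)
                else:
                    tri = 0.0
                err += (h - tri) ** 2
            if err < best_err - 1e-12:
                best_err, best_tinn = err, m_edge - n_edge
    return best_tinn


class TestGeometricIndices:
    def test_single_bin_degenerate(self):
        hist = RrHistogram(bin_edges=np.array([796.875, 804.6875]),
                           counts=np.array([128]), mode_bin=0)
        hrv_ti, tinn = geometric_indices(hist)
        assert hrv_ti == 1.0 and tinn == 0.0

    def test_uniform_four_bins_ratio(self):
        edges = 800.0 + DEFAULT_BIN_WIDTH_MS * np.arange(5)
        hist = RrHistogram(bin_edges=edges,
                           counts=np.array([32, 32, 32, 32]), mode_bin=0)
        hrv_ti, _ = geometric_indices(hist)
        assert hrv_ti == pytest.approx(4.0)

    def test_symmetric_triangle_recovered_within_one_bin(self):
        width = DEFAULT_BIN_WIDTH_MS
        edges = 700.0 + width * np.arange(10)
        counts = np.array([10, 20, 30, 40, 50, 40, 30, 20, 10])
        hist = RrHistogram(bin_edges=edges, counts=counts, mode_bin=4)
        _, tinn = geometric_indices(hist)
        assert abs(tinn - 9 * width) <= width

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 40, size=12)
            counts[rng.integers(0, 12)] += 50  # ensure a clear mode
            edges = 600.0 + DEFAULT_BIN_WIDTH_MS * np.arange(13)
            hist = RrHistogram(bin_edges=edges, counts=counts,
                               mode_bin=int(np.argmax(counts)))
            _, tinn = geometric_indices(hist)
            assert tinn == pytest.approx(
                oracle_triangle_fit(counts, edges), abs=1e-9)
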