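"""Recurrence matrix and RQA versus a naive double-loop oracle."""

import numpy as np
import pytest

from hrvlab import (
    CohortSpec,
    RqaConfig,
    RrSeries,
    ValidationError,
    generate_rr,
    recurrence_matrix,
    rqa,
    rqa_from_rr,
)


def oracle_rqa(matrix, l_min=2, v_min=2):
    """Naive O(N^2) scan, fully independent of the implementation."""
    n = matrix.shape[0]
    off = matrix.astype(bool).copy()
    for i in range(n):
        off[i, i] = False
    recurrent = int(off.sum())
    rec = 100.0 * recurrent / (n * n - n)
    diag, vert = {}, {}
    for k in list(range(-n + 1, 0)) + list(range(1, n)):
        run = 0
        idx = [(i, i + k) for i in range(n) if 0 <= i + k < n]
        for i, j in idx:
            if off[i, j]:
                run += 1
            else:
                if run:
                    diag[run] = diag.get(run, 0) + 1
                run = 0
        if run:
            diag[run] = diag.get(run, 0) + 1
    for j in range(n):
        run = 0
        for i in range(n):
            if off[i, j]:
                run += 1
            else:
                if run:
                    vert[run] = vert.get(run, 0) + 1
                run = 0
        if run:
            vert[run] = vert.get(run, 0) + 1
    if recurrent == 0:
        return {"rec": 0.0, "det": None, "lam": None, "entr": None,
                "diag": {}, "vert": {}}
    det = 100.0 * sum(l * c for l, c in diag.items() if l >= l_min) / recurrent
    lam = 100.0 * sum(l * c for l, c in vert.items() if l >= v_min) / recurrent
    long_counts = [c for l, c in sorted(diag.items()) if l >= l_min]
    if long_counts:
        p = np.array(long_counts) / sum(long_counts)
        entr = float(-(p * np.log(p)).sum())
    else:
        entr = None
    return {"rec": rec, "det": det, "lam": lam, "entr": entr,
            "diag": {l: c for l, c in diag.items() if l >= l_min},
            "vert": {l: c for l, c in vert.items() if l >= v_min}}


class TestRecurrenceMatrix:
    def test_constant_series_all_ones(self):
        m = recurrence_matrix(np.full(10, 5.0), m=1, epsilon=0.5)
        assert m.all()

    def test_parity_pattern(self):
        m = recurrence_matrix(np.array([0, 1, 0, 1, 0, 1], dtype=float),
                              m=1, epsilon=0.5)
        i, j = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        np.testing.assert_array_equal(m, (i % 2) == (j % 2))

    def test_symmetric_with_unit_diagonal(self, rng):
        x = rng.normal(size=80)
        m = recurrence_matrix(x, m=2, tau=3, epsilon=0.7)
        assert (m == m.T).all()
        assert m.diagonal().all()

    def test_insufficient_length_rejected(self):
        with pytest.raises(ValidationError):
            recurrence_matrix(np.arange(5, dtype=float), m=3, tau=3,
                              epsilon=1.0)


class TestRqa:
    def test_all_ones_matrix_saturates(self):
        # Every cell recurrent; the two single-cell corner diagonals fall
        # below l_min, so DET/LAM saturate at 88/90 of the off-identity
        # points rather than at exactly 100% — confirmed by the oracle.
        rep = rqa(np.ones((10, 10), dtype=bool))
        ref = oracle_rqa(np.ones((10, 10), dtype=bool))
        assert rep.rec == 100.0
        assert rep.det == pytest.approx(ref["det"], rel=1e-12)
        assert rep.det == pytest.approx(100.0 * 88 / 90, rel=1e-12)
        assert rep.lam == pytest.approx(ref["lam"], rel=1e-12)

    def test_single_diagonal_line(self):
        m = np.eye(12, dtype=bool)
        for i in range(5):
            m[i, i + 4] = m[i + 4, i] = True  # one diagonal of length 5
        rep = rqa(m)
        assert rep.diag_hist == {5: 2}  # both triangle copies
        assert rep.entr == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_matches_oracle(self):
        m = recurrence_matrix(np.array([0, 1, 0, 1, 0, 1], dtype=float),
                              m=1, epsilon=0.5)
        rep = rqa(m)
        ref = oracle_rqa(m)
        assert rep.rec == pytest.approx(ref["rec"], rel=1e-12)
        assert rep.det == pytest.approx(ref["det"], rel=1e-12)

    def test_random_matrices_match_oracle_exactly(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 200))
            x = rng.normal(size=n)
            eps = float(rng.uniform(0.3, 1.5))
            m_dim = int(rng.integers(1, 4))
            if n <= (m_dim - 1) * 2 + 1:
                continue
            m = recurrence_matrix(x, m=m_dim, tau=2, epsilon=eps)
            rep = rqa(m)
            ref = oracle_rqa(m)
            assert rep.rec == pytest.approx(ref["rec"], rel=1e-12)
            assert rep.diag_hist == ref["diag"]
            assert rep.vert_hist == ref["vert"]
            if ref["det"] is None:
                assert rep.det is None
            else:
                assert rep.det == pytest.approx(ref["det"], rel=1e-12)
                assert rep.lam == pytest.approx(ref["lam"], rel=1e-12)
                if ref["entr"] is None:
                    assert rep.entr is None
                else:
                    assert rep.entr == pytest.approx(ref["entr"], rel=1e-9)

    def test_rec_monotone_in_epsilon(self, rng):
        x = rng.normal(size=120)
        recs = [rqa(recurrence_matrix(x, m=2, tau=1, epsilon=e)).rec
                for e in (0.2, 0.5, 1.0, 2.0, 4.0)]
        assert all(a <= b for a, b in zip(recs, recs[1:]))

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, 1] = True
        np.fill_diagonal(m, True)
        with pytest.raises(ValidationError):
            rqa(m)


class TestRqaFromRr:
    def _periodic_rr(self, seed=0):
        rr, _ = generate_rr(
            CohortSpec(mean_rr=800.0, rsa_amp=40.0, rsa_freq=0.25,
                       noise_sd=0.0, seed=seed), 300)
        return RrSeries(rr.intervals, rr.beat_times, is_nn=True)

    def _noise_rr(self, seed=0):
        rng = np.random.default_rng(seed)
        return RrSeries.from_intervals(rng.uniform(700, 900, 370), is_nn=True)

    def test_periodic_series_highly_deterministic(self):
        cfg = RqaConfig(m=3, tau=1)
        rep = rqa_from_rr(self._periodic_rr(), cfg)
        assert rep.det >= 95.0

    def test_noise_less_deterministic_than_periodic(self):
        cfg = RqaConfig(m=3, tau=1)
        det_periodic = rqa_from_rr(self._periodic_rr(), cfg).det
        det_noise = rqa_from_rr(self._noise_rr(), cfg).det
        assert det_noise < det_periodic

    def test_deterministic_given_fixed_config(self):
        cfg = RqaConfig(m=3, tau=2, epsilon_frac=0.15)
        rr = self._periodic_rr(3)
        a = rqa_from_rr(rr, cfg)
        b = rqa_from_rr(rr, cfg)
        assert a == b

    def test_settings_recorded(self):
        rep = rqa_from_rr(self._periodic_rr(), RqaConfig(m=2, tau=1))
        assert rep.settings["m"] == 2 and rep.settings["tau"] == 1
        assert rep.settings["epsilon"] > 0

    def test_short_series_rejected(self):
        rr = RrSeries.from_intervals(np.full(30, 800.0), is_nn=True)
        with pytest.raises(ValidationError):
            rqa_from_rr(rr, RqaConfig(m=2, tau=1))
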