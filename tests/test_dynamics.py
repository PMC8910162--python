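"""Lifetimes, end speeds, normalized counts, smoothing and paired tests."""

import numpy as np
import pytest

from filoscaffold.detection import FilopodiumDetection, IsletRecord
from filoscaffold.dynamics import (KineticCurve, end_speeds, fraction_elongating,
                                   interval_means, normalized_count,
                                   paired_significance_test,
                                   smooth_kinetic_curve, summarize_movie,
                                   track_lifetimes)
from filoscaffold.io import ImageMeta
from filoscaffold.tracking import FilopodiumTrack


def make_track(frames, censored_start=False, censored_end=False,
               minus=None, plus=None):
    t = FilopodiumTrack(id=0, steps=[(f, 0) for f in frames],
                        censored_start=censored_start, censored_end=censored_end)
    if minus is not None:
        t.minus_end = [np.asarray(p, float) for p in minus]
        t.plus_end = [np.asarray(p, float) for p in plus]
    return t


class TestTrackLifetimes:
    def test_inclusive_frame_count(self):
        t = make_track(range(10, 20))
        assert track_lifetimes([t], 20.0)[0] == pytest.approx(200.0)

    def test_censored_tracks_never_contribute(self):
        tracks = [make_track(range(0, 5), censored_start=True),
                  make_track(range(5, 9)),
                  make_track(range(9, 12), censored_end=True)]
        lt = track_lifetimes(tracks, 20.0)
        assert lt.tolist() == [80.0]

    def test_all_censored_warns_empty(self):
        tracks = [make_track(range(0, 5), censored_start=True)]
        with pytest.warns(UserWarning):
            lt = track_lifetimes(tracks, 20.0)
        assert len(lt) == 0

    def test_exponential_lifetime_estimator_bias(self):
        """Movies 20x the mean lifetime: the censoring-exclusion estimator
        recovers exponential lifetimes within 5%."""
        rng = np.random.default_rng(99)
        dt, mean_lt = 20.0, 230.0
        n_frames = int(20 * mean_lt / dt)
        est = []
        for _ in range(40):
            births = rng.uniform(0, n_frames * dt, size=300)
            lifes = rng.exponential(mean_lt, size=300)
            tracks = []
            for b, L in zip(births, lifes):
                f0 = int(np.ceil(b / dt))
                f1 = int(np.floor((b + L) / dt))
                if f1 < f0:
                    continue
                f1c = min(f1, n_frames - 1)
                tracks.append(make_track(range(f0, f1c + 1),
                                         censored_start=f0 <= 0,
                                         censored_end=f1 >= n_frames - 1))
            est.append(track_lifetimes(tracks, dt).mean())
        bias = (np.mean(est) - mean_lt) / mean_lt
        assert abs(bias) < 0.05


class TestEndSpeeds:
    def test_outward_tip_45nms(self):
        """Tip moving 0.9 um outward per 20 s frame: (+)-elongation 45 nm/s
        and no (-)-end events for a static base."""
        px = 0.3
        step = 0.9 / px  # px per frame
        n = 6
        minus = [(10.0, 5.0)] * n
        plus = [(10.0, 5.0 + 3 + i * step) for i in range(n)]
        t = make_track(range(n), minus=minus, plus=plus)
        sp = end_speeds(t, 20.0, px)
        assert sp["elong_plus"] == pytest.approx(45.0, rel=1e-9)
        assert np.isnan(sp["retract_plus"])
        assert np.isnan(sp["elong_minus"])
        assert np.isnan(sp["retract_minus"])

    def test_static_filopodium_no_events(self):
        n = 5
        t = make_track(range(n), minus=[(5, 5)] * n, plus=[(5, 15)] * n)
        sp = end_speeds(t, 20.0, 0.3)
        assert all(np.isnan(v) for v in sp.values())

    def test_single_frame_rejected(self):
        t = make_track([3], minus=[(0, 0)], plus=[(0, 5)])
        with pytest.raises(ValueError):
            end_speeds(t, 20.0, 0.3)

    def test_time_offset_invariance(self):
        px = 0.3
        n = 6
        minus = [(10.0, 5.0)] * n
        plus = [(10.0, 8.0 + i * 3) for i in range(n)]
        a = make_track(range(n), minus=minus, plus=plus)
        b = make_track(range(50, 50 + n), minus=minus, plus=plus)
        sa, sb = end_speeds(a, 20.0, px), end_speeds(b, 20.0, px)
        for k in sa:
            assert sa[k] == pytest.approx(sb[k], nan_ok=True)


class TestNormalizedCount:
    def _islet(self, perim):
        return IsletRecord(frame=0, label=1, mask=np.ones((4, 4), bool),
                           perimeter_um=perim, area_um2=10.0)

    def _det(self):
        px = np.array([[0, 0], [0, 1]])
        return FilopodiumDetection(frame=0, id=0, pixels=px, path=px,
                                   base=px[0].astype(float),
                                   tip=px[1].astype(float), length_um=1.0,
                                   orientation_deg=0.0, islet=1)

    def test_ten_over_250(self):
        v = normalized_count([self._det()] * 10, [self._islet(250.0)])
        assert v == pytest.approx(0.04)

    def test_doubling_perimeter_halves_value(self):
        dets = [self._det()] * 7
        v1 = normalized_count(dets, [self._islet(100.0)])
        v2 = normalized_count(dets, [self._islet(200.0)])
        assert v1 == pytest.approx(2 * v2)

    def test_no_islets_rejected(self):
        with pytest.raises(ValueError):
            normalized_count([self._det()], [])


class TestSmoothing:
    def test_cubic_reproduced_exactly(self):
        t = np.arange(200.0)
        y = 1e-3 * t**3 - 0.2 * t**2 + 7 * t - 3
        c = smooth_kinetic_curve(t, y, window=21, degree=3)
        assert np.max(np.abs(c.smoothed - y)) <= 1e-9 * np.max(np.abs(y))

    def test_constant_unchanged(self):
        t = np.arange(50.0)
        c = smooth_kinetic_curve(t, np.full(50, 3.3))
        assert np.allclose(c.smoothed, 3.3)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(5)
        t = np.arange(300.0)
        clean = 1e-6 * t**3 - 1e-3 * t**2 + 0.1 * t
        noisy = clean + rng.normal(0, 1.0, size=t.size)
        c = smooth_kinetic_curve(t, noisy)
        resid = c.smoothed - clean
        assert resid.std() < 1.0 * 0.6

    @pytest.mark.parametrize("window,n", [(20, 100), (21, 10), (3, 100)])
    def test_invalid_window_rejected(self, window, n):
        t = np.arange(float(n))
        with pytest.raises(ValueError):
            smooth_kinetic_curve(t, t, window=window, degree=3)


class TestIntervalMeans:
    def _curve(self, t, v, quantity=""):
        v = np.asarray(v, float)
        return KineticCurve(time_s=np.asarray(t, float), raw=v, smoothed=v,
                            quantity=quantity)

    def test_constant_curve(self):
        t = np.arange(0, 7000, 20.0)
        c = self._curve(t, np.full(t.size, 4.2))
        assert interval_means(c, 2400.0) == (pytest.approx(4.2), pytest.approx(4.2))

    def test_step_curve(self):
        t = np.arange(0, 7000, 20.0)
        v = np.where(t < 2400.0, 1.0, 3.0)
        ctr, drug = interval_means(self._curve(t, v), 2400.0)
        assert ctr == pytest.approx(1.0)
        assert drug == pytest.approx(3.0)

    def test_piecewise_linear_window_means_analytic(self):
        """Window means equal the analytic mid-window values of a ramp."""
        t = np.arange(0, 8000, 20.0)
        v = 0.001 * t
        drug_time = 2400.0
        ctr, drug = interval_means(self._curve(t, v), drug_time)
        w = 10.3 * 60
        assert ctr == pytest.approx(0.001 * (drug_time - w / 2), rel=0.01)
        start = drug_time + 21.3 * 60
        assert drug == pytest.approx(0.001 * (start + w / 2), rel=0.01)

    def test_lifetime_window_shifted_5min(self):
        t = np.arange(0, 8000, 20.0)
        v = 0.001 * t
        drug_time = 2400.0
        ctr, _ = interval_means(self._curve(t, v, quantity="lifetime"), drug_time)
        w = 10.3 * 60
        assert ctr == pytest.approx(0.001 * (drug_time - 300 - w / 2), rel=0.01)

    def test_slow_onset_window(self):
        t = np.arange(0, 8000, 20.0)
        v = 0.001 * t
        _, drug = interval_means(self._curve(t, v), 2400.0, slow_onset=True)
        start = 2400.0 + 40 * 60
        assert drug == pytest.approx(0.001 * (start + 10.3 * 60 / 2), rel=0.01)

    def test_window_outside_span_rejected(self):
        t = np.arange(0, 1000, 20.0)
        with pytest.raises(ValueError):
            interval_means(self._curve(t, t), 900.0)


class TestPairedTest:
    def test_closed_form_small_sample(self):
        """Differences (1, 2, 0): t = sqrt(3), df = 2, two-sided p = 0.2254."""
        shapiro_p, t, p = paired_significance_test([1, 2, 3], [2, 4, 3])
        assert t == pytest.approx(np.sqrt(3.0), rel=1e-9)
        assert p == pytest.approx(0.22540333, rel=1e-6)

    def test_degenerate_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_significance_test([1, 2, 3], [2, 3, 4])

    def test_type_one_error_calibrated(self):
        """Null replicates at n = 5: rejection rate consistent with 0.05."""
        rng = np.random.default_rng(11)
        n_rep = 2000
        rej = 0
        for _ in range(n_rep):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0, 1, 5)
            _, _, p = paired_significance_test(a, b)
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < 3 * se + 1e-12


class TestSummarizeMovie:
    def _simple_movie(self):
        """One deterministic triangle filopodium over 7 frames."""
        px, dt = 0.3, 20.0
        meta = ImageMeta(pixel_size=px, frame_interval=dt)
        lengths = [1.2, 2.1, 3.0, 3.0, 2.1, 1.2]
        dets = {}
        islets = {}
        base = np.array([20.0, 10.0])
        for f, L in enumerate([np.nan] + lengths + [np.nan]):
            islets[f] = [IsletRecord(frame=f, label=1,
                                     mask=np.zeros((40, 40), bool),
                                     perimeter_um=100.0, area_um2=50.0)]
            if np.isnan(L):
                dets[f] = []
                continue
            tip = base + np.array([0.0, L / px])
            pix = np.array([[20, c] for c in range(10, int(tip[1]) + 1)])
            dets[f] = [FilopodiumDetection(frame=f, id=0, pixels=pix, path=pix,
                                           base=base.copy(), tip=tip,
                                           length_um=L, orientation_deg=0.0,
                                           islet=1)]
        track = make_track(range(1, 7),
                           minus=[base] * 6,
                           plus=[base + np.array([0, l / px]) for l in lengths])
        return track, dets, islets, meta

    def test_closed_form_single_filopodium(self):
        track, dets, islets, meta = self._simple_movie()
        s = summarize_movie([track], dets, islets, meta)
        assert s.n_filopodia == 1
        assert s.mean_length_um == pytest.approx(np.mean([1.2, 2.1, 3.0, 3.0, 2.1, 1.2]))
        assert s.mean_lifetime_s == pytest.approx(6 * 20.0)
        assert s.elong_speed_plus_nms == pytest.approx(45.0)
        assert s.retract_speed_plus_nms == pytest.approx(45.0)
        assert s.normalized_number_per_um == pytest.approx(6 / (8 * 100))
        # elongating on 2 of 5 frame pairs with a live predecessor
        assert s.fraction_elongating == pytest.approx(2 / 5)

    def test_empty_movie(self):
        meta = ImageMeta(pixel_size=0.3, frame_interval=20.0)
        s = summarize_movie([], {0: [], 1: []}, {0: [], 1: []}, meta)
        assert s.n_filopodia == 0
        assert np.isnan(s.mean_length_um)
        assert np.isnan(s.mean_lifetime_s)


class TestFractionElongating:
    def test_growth_above_noise_floor_counts(self):
        t = make_track([0, 1, 2])
        lengths = {(0, 0): 1.0, (1, 0): 2.0, (2, 0): 2.05}
        assert fraction_elongating([t], lengths, min_step_um=0.3) == pytest.approx(0.5)
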