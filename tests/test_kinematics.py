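"""Lip-aperture signal operations: Euclidean distance, resampling,
alignment, segmentation, normalization and the validation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipstereo import (
    AlignmentError,
    ApertureSeries,
    UtteranceWindow,
    accuracy_report,
    coarse_align,
    find_closure_minima,
    lip_aperture,
    normalize_offset,
    precision_sd,
    refine_align,
    resample,
    rmse,
    utterance_window,
)
from lipstereo.errors import LipStereoError
from lipstereo.synth import GestureParams, la_trajectory


def series(values, rate=250.0):
    return ApertureSeries(np.asarray(values, float), rate=rate)


class TestLipAperture:
    def test_coincident_points_give_zero(self):
        pts = np.zeros((5, 3))
        assert np.all(lip_aperture(pts, pts, rate=60).values == 0)

    def test_pythagorean_triple(self):
        la = lip_aperture([[0, 0, 0]], [[3, 4, 0]], rate=60)
        assert la.values[0] == 5.0

    def test_matches_independent_distance_oracle(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=(50, 3))
        l = rng.normal(size=(50, 3))
        # brute-force per-component oracle
        expected = np.sqrt(
            (u[:, 0] - l[:, 0]) ** 2 + (u[:, 1] - l[:, 1]) ** 2 + (u[:, 2] - l[:, 2]) ** 2
        )
        np.testing.assert_allclose(
            lip_aperture(u, l, rate=60).values, expected, atol=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(LipStereoError):
            lip_aperture(np.zeros((3, 3)), np.zeros((4, 3)), rate=60)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        u = rng.normal(scale=10, size=(20, 3))
        l = rng.normal(scale=10, size=(20, 3))
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        t = np.array([5.0, -8.0, 13.0])
        a = lip_aperture(u, l, rate=60).values
        b = lip_aperture(u @ R.T + t, l @ R.T + t, rate=60).values
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestResample:
    def test_identity_rate(self):
        s = series([1.0, 5.0, 2.0, 8.0], rate=60)
        out = resample(s, 60)
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_interpolation_by_hand(self):
        s = series([0.0, 10.0], rate=1.0)
        out = resample(s, 5.0)
        np.testing.assert_allclose(out.values, [0, 2, 4, 6, 8, 10])

    def test_constant_stays_constant(self):
        s = series(np.full(30, 4.2), rate=60)
        assert np.allclose(resample(s, 250).values, 4.2)

    def test_invalid_rate(self):
        with pytest.raises(LipStereoError):
            resample(series([1, 2]), -1)


class TestCoarseAlign:
    def test_identical(self):
        s = series([0, 1, 5, 1, 0])
        assert coarse_align(s, s) == 0

    def test_peak_shift(self):
        a = series([0, 1, 5, 1, 0, 0, 0, 0, 0, 0])
        b = series(np.roll(a.values, 7))
        assert coarse_align(a, b) == 7

    def test_noisy_peak_recovery(self):
        # At the 60 Hz video rate the raised-cosine peak drops far more per
        # sample than 0.1 mm of noise, so the argmax stagger is recovered
        # exactly.
        rng = np.random.default_rng(11)
        base = la_trajectory(GestureParams.template("puppy"), fps=60).values
        n = len(base)
        a = series(base + rng.normal(0, 0.1, n), rate=60)
        b = series(
            np.concatenate([np.full(11, base[0]), base[:-11]])
            + rng.normal(0, 0.1, n),
            rate=60,
        )
        assert coarse_align(a, b) == 11

    def test_empty_errors(self):
        with pytest.raises(AlignmentError):
            coarse_align(series([1, 2]), ApertureSeries(np.zeros(0), rate=250))


class TestRefineAlign:
    def test_exact_shift_recovery_all_lags(self):
        base = la_trajectory(GestureParams.template("puppy"), fps=250).values
        n = len(base)
        a = base[30 : n - 30]
        for k in range(-20, 21):
            b = base[30 + k : n - 30 + k]
            res = refine_align(a, b, initial_lag=0, max_shift=30)
            assert res.lag == -k
            assert res.rmse_at_lag < 1e-12

    def test_exact_match_wins_outright(self):
        v = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], dtype=float)
        res = refine_align(v, v, initial_lag=0, max_shift=2, min_overlap=5)
        assert res.lag == 0

    def test_tie_breaks_to_more_negative(self):
        # Period-4 wave vs its antiphase copy: shifts +2 and -2 both achieve
        # RMSE 0 (same overlap length), so |lag| ties and the more negative
        # lag must win.
        a = np.sin(2 * np.pi * np.arange(16) / 4.0)
        b = -a
        res = refine_align(a, b, initial_lag=0, max_shift=3, min_overlap=5)
        assert res.lag == -2
        assert res.rmse_at_lag < 1e-12

    def test_shift_equivariance(self):
        base = la_trajectory(GestureParams.template("puppy"), fps=250).values
        a = base[40:-40]
        b0 = base[40:-40]
        r0 = refine_align(a, b0, 0, 10).lag
        m = 6
        bm = base[40 - m : -40 - m]
        assert refine_align(a, bm, 0, 10).lag == r0 + m

    def test_insufficient_overlap(self):
        with pytest.raises(AlignmentError):
            refine_align(np.arange(5.0), np.arange(5.0), initial_lag=100, max_shift=2)

    def test_noisy_lag_recovery_rate(self):
        """Known 13-sample lag with 0.2 mm LA noise: recovered in >= 99% of
        100 seeded replicates."""
        base = la_trajectory(GestureParams.template("puppy"), fps=250).values
        n = len(base)
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            a = base[40 : n - 40] + rng.normal(0, 0.2, n - 80)
            b = base[40 - 13 : n - 40 - 13] + rng.normal(0, 0.2, n - 80)
            res = refine_align(a, b, coarse_align(series(a), series(b)), 50)
            hits += res.lag == 13
        assert hits >= 99


class TestClosureMinima:
    def test_monotone_series_has_none(self):
        assert len(find_closure_minima(np.arange(10.0), 0.5)) == 0

    def test_alternating_series(self):
        idx = find_closure_minima(np.array([5.0, 1, 5, 1, 5]), 1.0)
        np.testing.assert_array_equal(idx, [1, 3])

    def test_puppy_template_boundaries(self):
        params = GestureParams.template("puppy")
        la = la_trajectory(params, fps=60)
        idx = find_closure_minima(la.values, 2.0, min_separation=5)
        onsets = [g[0] for g in params.gestures]
        expected = [round(t * 60) for t in onsets[1:]]
        assert len(idx) == 2
        for i, e in zip(idx, expected):
            assert abs(i - e) <= 1

    def test_separation_keeps_deeper(self):
        v = np.array([5.0, 1.0, 4.0, 0.5, 5.0, 5.0, 5.0])
        idx = find_closure_minima(v, 0.4, min_separation=4)
        np.testing.assert_array_equal(idx, [3])


class TestUtteranceWindow:
    def test_first_last(self):
        w = utterance_window([10, 50])
        assert (w.onset_index, w.offset_index) == (10, 50)

    def test_first_last_ignores_interior(self):
        w = utterance_window([10, 30, 50])
        assert (w.onset_index, w.offset_index) == (10, 50)

    def test_single_minimum_errors(self):
        with pytest.raises(AlignmentError):
            utterance_window([10])

    def test_explicit_mode(self):
        w = utterance_window([10, 30, 50], mode="explicit", select=(0, 1))
        assert (w.onset_index, w.offset_index) == (10, 30)


class TestNormalizeOffset:
    def test_identity(self):
        s = series([1.0, 2, 3, 4, 5])
        out, res = normalize_offset(s, s, UtteranceWindow(0, 4))
        assert res.additive_offset == 0.0
        np.testing.assert_array_equal(out.values, s.values)

    def test_constant_shift_recovered_exactly(self):
        ref = series([3.0, 4, 5, 6])
        s = series([1.0, 2, 3, 4])
        out, res = normalize_offset(s, ref, UtteranceWindow(0, 3))
        assert res.additive_offset == 2.0
        np.testing.assert_array_equal(out.values, ref.values)

    def test_window_means_match_to_fp(self):
        rng = np.random.default_rng(5)
        s = series(rng.uniform(0, 10, 100))
        ref = series(rng.uniform(0, 10, 100))
        w = UtteranceWindow(10, 80)
        out, _ = normalize_offset(s, ref, w)
        ms = np.mean(out.values[w.slice()])
        mr = np.mean(ref.values[w.slice()])
        assert abs(ms - mr) < 1e-12 * max(1.0, abs(mr))

    def test_shape_preserved(self):
        rng = np.random.default_rng(6)
        s = series(rng.uniform(0, 10, 50))
        ref = series(rng.uniform(0, 10, 50))
        out, _ = normalize_offset(s, ref, UtteranceWindow(0, 49))
        np.testing.assert_allclose(np.diff(out.values), np.diff(s.values))
        assert abs(precision_sd(out) - precision_sd(s)) < 1e-12


class TestRmse:
    def test_identical_is_zero(self):
        assert rmse([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_hand_computed(self):
        assert abs(rmse([1.0, 2, 3], [2.0, 2, 3]) - np.sqrt(1 / 3)) < 1e-15

    def test_constant_offset_closed_form(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 5, 40)
        assert abs(rmse(a, a + 1.75) - 1.75) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(LipStereoError):
            rmse([1.0, 2], [1.0, 2, 3])


class TestPrecisionSd:
    def test_constant_is_zero(self):
        assert precision_sd(np.full(10, 3.3)) == 0.0

    def test_sample_divisor(self):
        assert precision_sd([1.0, 2.0, 3.0]) == 1.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(size=30)
        assert abs(precision_sd(v) - precision_sd(v + 100.0)) < 1e-12

    def test_too_short(self):
        with pytest.raises(LipStereoError):
            precision_sd([1.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_rmse_symmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 10, 25)
    b = rng.uniform(0, 10, 25)
    assert rmse(a, b) == rmse(b, a)
    assert rmse(a, b) >= 0.0


class TestAccuracyReport:
    def test_self_comparison(self):
        ref = la_trajectory(GestureParams.template("puppy"), fps=250)
        rep = accuracy_report(ref, ref, min_prominence=2.0)
        assert rep.alignment.lag == 0
        assert rep.additive_offset_mm == 0.0
        assert rep.rmse_mm == 0.0

    def test_known_offset_and_lag_recovered(self):
        gt = la_trajectory(GestureParams.template("puppy"), fps=60)
        test = resample(gt, 250)
        lag, offset = 9, 1.5
        v = test.values + offset
        ref = ApertureSeries(
            np.concatenate([np.full(lag, v[0]), v[:-lag]]), rate=250
        )
        rep = accuracy_report(test, ref, min_prominence=2.0)
        assert rep.alignment.lag == lag
        assert abs(rep.additive_offset_mm - offset) < 1e-9
        assert rep.rmse_mm < 1e-9

    def test_rmse_concentrates_at_reference_noise_sd(self):
        """With iid reference noise of SD sigma the final RMSE approaches
        sigma (averaged over seeded replicates)."""
        gt = la_trajectory(GestureParams.template("puppy"), fps=60)
        test = resample(gt, 250)
        sigma = 0.3
        vals = []
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            ref = ApertureSeries(test.values + rng.normal(0, sigma, len(test)),
                                 rate=250)
            r = accuracy_report(test, ref, min_prominence=2.0, max_shift=5)
            vals.append(r.rmse_mm)
        assert abs(np.mean(vals) - sigma) / sigma < 0.15
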