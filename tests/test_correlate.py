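"""Phase segmentation and the phase-split polynomial correlation model."""

import numpy as np
import pytest

from respivox import (
    compare_surrogates,
    evaluate_mse,
    fit_model,
    predict,
    segment_phases,
)
from respivox.correlate import EXHALE, INHALE
from respivox.errors import AlignmentError, FlatSignalError, InsufficientDataError


def sinusoid(n_periods=3, frames_per_period=100):
    t = np.arange(n_periods * frames_per_period) / frames_per_period
    return t, np.sin(2 * np.pi * t)


def denormalized_coeffs(model, branch="exhale"):
    """Map fitted coefficients back to raw-surrogate polynomial basis."""
    c = model.coeffs_exhale if branch == "exhale" else model.coeffs_inhale
    # substitute u = (r - mu)/s into sum c_j u^j
    mu, s = model.surrogate_shift, model.surrogate_scale
    poly = np.polynomial.polynomial.Polynomial(c)(
        np.polynomial.polynomial.Polynomial([-mu / s, 1.0 / s])
    )
    return poly.coef


class TestSegmentPhases:
    def test_sinusoid_extrema_positions(self):
        t, r = sinusoid()
        seg = segment_phases(r, smooth_window=1)
        peaks = seg.extrema_indices[seg.extrema_kinds == 1]
        valleys = seg.extrema_indices[seg.extrema_kinds == -1]
        assert len(peaks) == 3 and len(valleys) == 3
        for p in peaks:
            assert min(abs(p - 100 * (n + 0.25)) for n in range(3)) <= 1
        for v in valleys:
            assert min(abs(v - 100 * (n + 0.75)) for n in range(3)) <= 1

    def test_labels_partition_all_frames(self):
        _, r = sinusoid()
        seg = segment_phases(r)
        assert len(seg.labels) == len(r)
        assert set(np.unique(seg.labels)) <= {EXHALE, INHALE}
        # descent after a peak is exhale, ascent after a valley inhale
        p0 = seg.extrema_indices[seg.extrema_kinds == 1][0]
        v0 = seg.extrema_indices[seg.extrema_kinds == -1][0]
        assert seg.labels[p0 + 5] == EXHALE
        assert seg.labels[v0 + 5] == INHALE

    def test_extrema_alternate(self):
        rng = np.random.default_rng(0)
        _, r = sinusoid()
        seg = segment_phases(r + rng.normal(0, 0.05, len(r)), smooth_window=7)
        assert np.all(seg.extrema_kinds[1:] != seg.extrema_kinds[:-1])

    def test_monotone_ramp_raises(self):
        with pytest.raises(FlatSignalError):
            segment_phases(np.linspace(0, 1, 50))

    def test_dividing_values_are_surrogate_at_extrema(self):
        _, r = sinusoid()
        seg = segment_phases(r, smooth_window=1)
        np.testing.assert_array_equal(seg.k, r[seg.extrema_indices])


class TestFitPredict:
    def test_linear_coupling_exact_recovery(self):
        _, r = sinusoid()
        xt = 2.0 + 3.0 * r
        seg = segment_phases(r)
        model = fit_model(r, xt, seg, N=1)
        for branch in ("exhale", "inhale"):
            np.testing.assert_allclose(denormalized_coeffs(model, branch), [2.0, 3.0], atol=1e-9)
        np.testing.assert_allclose(predict(model, r, seg), xt, atol=1e-9)

    def test_constant_target(self):
        _, r = sinusoid()
        model = fit_model(r, np.full(len(r), 7.0), segment_phases(r), N=2)
        np.testing.assert_allclose(denormalized_coeffs(model), [7.0, 0.0, 0.0], atol=1e-9)

    def test_quadratic_exact_with_matching_degree(self):
        _, r = sinusoid()
        xt = r**2
        seg = segment_phases(r)
        m2 = fit_model(r, xt, seg, N=2)
        np.testing.assert_allclose(predict(m2, r, seg), xt, atol=1e-9)
        m1 = fit_model(r, xt, seg, N=1)
        assert evaluate_mse(predict(m1, r, seg), xt) > 1e-3

    def test_degree_limits(self):
        _, r = sinusoid()
        xt = r.copy()
        seg = segment_phases(r)
        with pytest.raises(ValueError, match="overfitting"):
            fit_model(r, xt, seg, N=4)
        with pytest.raises(ValueError):
            fit_model(r, xt, seg, N=0)

    def test_underdetermined_phase_raises(self):
        r = np.array([0.0, 1.0, 0.5, 0.0, 1.0])
        xt = r.copy()
        seg = segment_phases(np.sin(np.linspace(0, 4 * np.pi, 5)), min_prominence=0.01, smooth_window=1)
        with pytest.raises(InsufficientDataError):
            fit_model(r, xt, seg, N=3)

    def test_hysteresis_gives_branch_disagreement(self):
        # lagged target: same surrogate value maps to different positions on
        # inhale vs exhale; the two fitted branches must differ
        t = np.arange(400) / 100.0
        r = np.sin(2 * np.pi * t / 2.0)
        xt = np.sin(2 * np.pi * (t - 0.15) / 2.0)
        seg = segment_phases(r)
        model = fit_model(r, xt, seg, N=2)
        rn = model.normalize(np.array([0.0]))
        up = np.polynomial.polynomial.polyval(rn, model.coeffs_inhale)
        down = np.polynomial.polynomial.polyval(rn, model.coeffs_exhale)
        assert abs(up - down) > 0.1

    def test_unsplit_baseline_uses_single_polynomial(self):
        _, r = sinusoid()
        xt = 1.0 + 2.0 * r
        model = fit_model(r, xt, None, N=1)
        np.testing.assert_array_equal(model.coeffs_exhale, model.coeffs_inhale)


class TestEvaluateMse:
    def test_exact_and_offset(self):
        x = np.arange(10.0)
        assert evaluate_mse(x, x) == 0.0
        assert evaluate_mse(x + 1.0, x) == 1.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 37))
        manual = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / 37
        assert evaluate_mse(a, b) == pytest.approx(manual, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            evaluate_mse(np.ones(3), np.ones(4))


class TestCompareSurrogates:
    def test_perfect_surrogate_beats_noisy_marker(self):
        rng = np.random.default_rng(0)
        t = np.arange(600) / 100.0
        tumor = np.sin(2 * np.pi * t / 2.0)
        report = compare_surrogates(
            marker_traj=tumor + rng.normal(0, 0.3, len(t)),
            reduced_feat=tumor,
            tumor=tumor,
            split=0.5,
        )
        assert report["winner_mse"] == "reduced_feature"
        assert report["winner_pearson"] == "reduced_feature"

    def test_identical_surrogates_tie_exactly(self):
        t = np.arange(600) / 100.0
        tumor = np.sin(2 * np.pi * t / 2.0)
        surrogate = np.sin(2 * np.pi * (t - 0.1) / 2.0)
        report = compare_surrogates(surrogate, surrogate, tumor)
        assert report["marker"]["test_mse"] == pytest.approx(
            report["reduced_feature"]["test_mse"], abs=1e-12
        )

    def test_phase_split_beats_unsplit_on_lagged_data(self):
        # hysteresis makes the single-polynomial baseline systematically
        # worse on held-out data, across seeded noise replicates
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.arange(800) / 100.0
            r = np.sin(2 * np.pi * t / 2.0) + rng.normal(0, 0.05, len(t))
            xt = np.sin(2 * np.pi * (t - 0.15) / 2.0)
            n = 400
            seg_tr = segment_phases(r[:n])
            seg_te = segment_phases(r[n:])
            split_mse = evaluate_mse(
                predict(fit_model(r[:n], xt[:n], seg_tr, 2), r[n:], seg_te), xt[n:]
            )
            unsplit_mse = evaluate_mse(
                predict(fit_model(r[:n], xt[:n], None, 2), r[n:], seg_te), xt[n:]
            )
            wins += split_mse <= unsplit_mse
        assert wins >= 9
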