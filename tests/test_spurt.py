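"""Dimension transforms, spurt landmarking on velocity curves, peak
alignment and hormone landmarks."""

import warnings

import numpy as np
import pytest

from growthscale.smoothing import fit_pspline
from growthscale.spurt import (
    SpurtSummary,
    VelocityCurve,
    detect_spurt,
    hormone_landmarks,
    peak_alignment,
    transform_dimension,
    velocity_curve,
)


class TestTransformDimension:
    def test_length_to_corrected(self):
        out = transform_dimension([10.0], "length_linear", "length_corrected", 2.5)
        assert out[0] == pytest.approx(316.22776601683796, rel=1e-12)

    def test_weight_downscale(self):
        out = transform_dimension([32.0], "weight", "weight_downscaled", 2.5)
        assert out[0] == pytest.approx(4.0, rel=1e-12)

    def test_round_trip_identity(self, rng):
        x = rng.uniform(0.1, 100, 50)
        back = transform_dimension(
            transform_dimension(x, "length_linear", "length_corrected", 2.5),
            "length_corrected", "length_linear", 2.5)
        assert back == pytest.approx(x, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            transform_dimension([-1.0], "length_linear", "length_corrected", 2.5)
        with pytest.raises(ValueError):
            transform_dimension([1.0], "length_linear", "weight", 2.5)
        with pytest.raises(ValueError):
            transform_dimension([1.0], "length_linear", "length_corrected", 5.0)


def _vc(t, v, **meta):
    return VelocityCurve(ages=np.asarray(t, float), velocity=np.asarray(v, float), **meta)


class TestDetectSpurt:
    def test_strictly_decreasing_velocity_not_detected(self):
        t = np.arange(0, 10, 0.1)
        s = detect_spurt(_vc(t, 5.0 * np.exp(-t / 3)))
        assert not s.detected and s.boundary_peak

    def test_bump_landmarks(self):
        t = np.arange(0, 20, 0.05)
        v = 1.0 + 0.2 * t + 3 * np.exp(-((t - 10) ** 2) / 2) - 0.15 * t
        s = detect_spurt(_vc(t, v))
        assert s.detected
        assert s.peak_age == pytest.approx(10.0, abs=0.1)
        assert s.take_off_age < s.peak_age
        assert s.cessation_age is None or s.cessation_age > s.peak_age

    def test_constant_velocity_not_detected(self):
        t = np.arange(0, 10, 0.1)
        s = detect_spurt(_vc(t, np.ones_like(t)))
        assert not s.detected

    def test_tied_maxima_take_earliest_and_flag(self):
        t = np.arange(0, 20, 0.1)
        v = np.exp(-((t - 5) ** 2)) + np.exp(-((t - 15) ** 2))
        s = detect_spurt(_vc(t, v))
        assert s.tied_peak
        assert s.peak_age == pytest.approx(5.0, abs=0.1)

    def test_small_rise_below_threshold_rejected(self):
        t = np.arange(0, 20, 0.05)
        v = 1.0 + 0.04 * np.exp(-((t - 10) ** 2) / 2)  # 4% rise < 10%
        s = detect_spurt(_vc(t, v))
        assert not s.detected

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_spurt(_vc([1, 2, 3], [1, 2, 1]))

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            SpurtSummary(take_off_age=5.0, peak_age=3.0, peak_velocity=1.0,
                         cessation_age=None, detected=True)


class TestScaleOrdering:
    @pytest.mark.parametrize("k", [2.0, 2.5, 3.0])
    def test_linear_peak_never_after_corrected_peak(self, reference, k):
        """Fit-based version of the lag >= 0 law on the noiseless latent curve."""
        t = np.arange(0.0, 25.0001, 0.25)
        S = reference.female.size.value(t)
        fit_corr = fit_pspline(t, S, lam=1e-6)
        fit_lin = fit_pspline(t, S ** (1 / k), lam=1e-6)
        vc_c = velocity_curve(fit_corr, grid_step=0.05, age_range=(0.5, 24.5))
        vc_l = velocity_curve(fit_lin, grid_step=0.05, age_range=(0.5, 24.5))
        pc = detect_spurt(vc_c).peak_age
        pl = detect_spurt(vc_l).peak_age
        assert pl <= pc + 0.05

    def test_transform_then_fit_commutes_with_fit_then_transform(self, reference):
        """Noiseless case: smoothing cm^k values or raising the fitted cm
        curve to k give the same corrected peak within grid resolution."""
        k = reference.k
        t = np.arange(0.0, 25.0001, 0.25)
        L = reference.female.size.value(t) ** (1 / k)
        fit_pre = fit_pspline(t, L**k, lam=1e-6)  # transform-then-fit
        fit_post = fit_pspline(t, L, lam=1e-6)  # fit-then-transform
        grid = np.arange(0.5, 24.5, 0.05)
        v_pre = fit_pre.derivative(grid)
        post_curve = fit_post.predict(grid) ** k
        v_post = np.gradient(post_curve, grid)
        p_pre = grid[np.argmax(v_pre)]
        p_post = grid[np.argmax(v_post)]
        assert p_pre == pytest.approx(p_post, abs=0.1)


class TestAlignment:
    @staticmethod
    def _summary(sex, var, dim, peak, detected=True):
        return SpurtSummary(take_off_age=2.0 if detected else None, peak_age=peak,
                            peak_velocity=1.0, cessation_age=None, detected=detected,
                            sex=sex, variable=var, dimension=dim)

    def test_identical_curves_zero_difference(self):
        s1 = self._summary("F", "weight_kg", "weight", 6.0)
        s2 = self._summary("F", "forearm_cm", "length_corrected", 6.0)
        tab = peak_alignment([s1, s2])
        assert tab["difference"].to_numpy() == pytest.approx([0.0])

    def test_undetected_excluded_with_warning(self):
        s1 = self._summary("M", "weight_kg", "weight", 8.0)
        s2 = self._summary("M", "creatinine", "log", 9.5)
        s3 = self._summary("M", "forearm_cm", "length_linear", None, detected=False)
        with pytest.warns(UserWarning):
            tab = peak_alignment([s1, s2, s3])
        assert len(tab) == 1
        assert tab["difference"].iloc[0] == pytest.approx(1.5)

    def test_needs_two_summaries(self):
        with pytest.raises(ValueError):
            peak_alignment([self._summary("F", "weight_kg", "weight", 6.0)])


class TestHormoneLandmarks:
    def test_constant_level_flat(self):
        t = np.linspace(0, 30, 200)
        fit = fit_pspline(t, np.full_like(t, 2.0), lam=1e-6)
        hl = hormone_landmarks(fit)
        assert hl.flat and hl.rise_fastest_age is None

    def test_sigmoid_rise_landmarks(self):
        from growthscale.smoothing import BasisSpec

        t = np.linspace(0, 30, 400)
        y = 2.0 / (1 + np.exp(-1.5 * (t - 7.0)))
        # enough knots that basis resolution does not blur the sharp rise
        fit = fit_pspline(t, y, spec=BasisSpec(n_knots=35), lam=1e-6)
        hl = hormone_landmarks(fit, grid_step=0.02)
        assert hl.rise_fastest_age == pytest.approx(7.0, abs=0.1)
        assert hl.plateau_age > 7.0
        assert hl.decline_onset_age is None  # monotone: no decline

    def test_rise_then_decline_detected(self):
        t = np.linspace(0, 45, 600)
        y = 2.0 / (1 + np.exp(-1.5 * (t - 7.0))) - 0.002 * np.clip(t - 30, 0, None) ** 2
        fit = fit_pspline(t, y, lam=1e-6)
        hl = hormone_landmarks(fit, grid_step=0.02)
        assert hl.decline_onset_age == pytest.approx(30.0, abs=1.5)
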