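"""Penalized B-spline smoother: exactness, GCV behaviour, edf, analytic
derivatives, grouped intercepts and bootstrap difference bands."""

import numpy as np
import pandas as pd
import pytest

from growthscale.smoothing import (
    BasisSpec,
    SmoothFit,
    difference_curve,
    fit_grouped,
    fit_pspline,
    fix_lambda_policy,
    lambda_for_edf,
)


@pytest.fixture()
def grid():
    return np.linspace(0.0, 10.0, 120)


class TestFitPspline:
    def test_quadratic_in_penalty_null_space_is_exact(self, grid):
        y = 2.0 + 0.5 * grid - 0.3 * grid**2
        fit = fit_pspline(grid, y, lam=1e-8)
        assert fit.predict(grid) == pytest.approx(y, abs=1e-6)

    def test_huge_lambda_converges_to_least_squares_line(self, grid, rng):
        y = 1.0 + 0.7 * grid + rng.normal(0, 0.1, len(grid))
        fit = fit_pspline(grid, y, lam=1e9)
        slope, intercept = np.polyfit(grid, y, 1)
        assert fit.predict(grid) == pytest.approx(intercept + slope * grid, abs=1e-3)
        assert fit.edf == pytest.approx(2.0, abs=0.05)

    def test_noiseless_spline_space_exact_at_lambda_zero(self, grid):
        spec = BasisSpec(n_knots=8)
        ref = fit_pspline(grid, np.sin(grid), spec=spec, lam=1e-6)
        y = ref.predict(grid)  # now exactly in the spline space
        fit = fit_pspline(grid, y, spec=spec, lam=0.0)
        assert fit.predict(grid) == pytest.approx(y, abs=1e-8)

    def test_auto_lambda_smooths_noise_harder_than_signal(self, rng):
        """Pure noise should be smoothed much harder than a strong sigmoid."""
        x = np.linspace(0, 10, 150)
        votes = 0
        for _ in range(20):
            lam_noise = fit_pspline(x, rng.normal(0, 1, len(x))).lam
            sig = 10.0 / (1 + np.exp(-2 * (x - 5))) + rng.normal(0, 1, len(x))
            lam_signal = fit_pspline(x, sig).lam
            votes += lam_noise > lam_signal
        assert votes > 10

    def test_input_validation(self, grid):
        with pytest.raises(ValueError):
            fit_pspline(grid, np.full_like(grid, np.nan))
        with pytest.raises(ValueError):
            fit_pspline(np.ones(10), np.ones(10))  # all ages identical
        with pytest.raises(ValueError):
            fit_pspline(grid, np.ones_like(grid), lam=-1.0)


class TestDerivative:
    def test_derivative_of_quadratic(self, grid):
        fit = fit_pspline(grid, grid**2, lam=1e-8)
        assert fit.derivative([5.0])[0] == pytest.approx(10.0, abs=1e-3)

    def test_derivative_of_constant_is_zero(self, grid):
        fit = fit_pspline(grid, np.full_like(grid, 3.0), lam=1e-8)
        assert np.max(np.abs(fit.derivative(grid))) < 1e-8

    def test_derivative_integrates_back_to_fit(self, grid, rng):
        y = np.sin(grid) + rng.normal(0, 0.05, len(grid))
        fit = fit_pspline(grid, y)
        lo, hi = np.quantile(grid, [0.05, 0.95])
        t = np.linspace(lo, hi, 400)
        integral = np.concatenate(
            [[0.0], np.cumsum((fit.derivative(t)[1:] + fit.derivative(t)[:-1]) / 2 * np.diff(t))])
        recon = fit.predict(t[0]) + integral
        scale = np.max(np.abs(fit.predict(t)))
        assert recon == pytest.approx(fit.predict(t), abs=1e-3 * scale)

    def test_reference_curve_velocity_argmax_matches_oracle(self, reference, oracle):
        """Noiseless female latent curve sampled every 0.25 y: the spline
        velocity peak lands within 0.1 y of the dense-grid oracle."""
        t = np.arange(0.0, 25.0001, 0.25)
        y = reference.female.size.value(t)
        fit = fit_pspline(t, y, lam=1e-6)
        dense = np.arange(0.1, 24.9, 0.01)
        peak = dense[np.argmax(fit.derivative(dense))]
        assert peak == pytest.approx(oracle.female.corrected_peak_age, abs=0.1)

    def test_extrapolation_refused(self, grid):
        fit = fit_pspline(grid, grid**2)
        with pytest.raises(ValueError):
            fit.predict([grid.max() + 1.0])
        with pytest.raises(ValueError):
            fit.derivative([grid.min() - 0.5])


def test_edf_strictly_decreases_in_lambda(grid, rng):
    y = np.sin(grid) + rng.normal(0, 0.1, len(grid))
    edfs = [fit_pspline(grid, y, lam=lam).edf for lam in 10.0 ** np.arange(-3, 6)]
    assert np.all(np.diff(edfs) < 0)


def test_lambda_for_edf_hits_target(grid, rng):
    y = np.sin(grid) + rng.normal(0, 0.1, len(grid))
    lam = lambda_for_edf(grid, y, 9.0)
    assert fit_pspline(grid, y, lam=lam).edf == pytest.approx(9.0, abs=0.5)


class TestGrouped:
    def test_offset_groups_recovered_and_centred(self, grid):
        x = np.concatenate([grid, grid])
        shape = np.sin(x / 2)
        offsets = np.concatenate([np.full_like(grid, 1.0), np.full_like(grid, -1.0)])
        groups = ["a"] * len(grid) + ["b"] * len(grid)
        fit = fit_grouped(x, shape + offsets, groups, lam=1e-4)
        assert fit.group_intercepts == pytest.approx([1.0, -1.0], abs=0.05)
        assert np.sum(fit.group_intercepts) == pytest.approx(0.0, abs=1e-8)
        assert fit.predict(grid) == pytest.approx(np.sin(grid / 2), abs=0.05)

    def test_zero_offsets_estimated_near_zero(self, grid, rng):
        x = np.concatenate([grid, grid])
        y = np.cos(x / 3) + rng.normal(0, 0.05, len(x))
        fit = fit_grouped(x, y, ["a"] * len(grid) + ["b"] * len(grid))
        assert np.max(np.abs(fit.group_intercepts)) < 0.05

    def test_single_group_degenerates_to_plain_fit(self, grid):
        y = grid**2
        fit = fit_grouped(grid, y, ["only"] * len(grid), lam=1e-8)
        assert fit.predict(grid) == pytest.approx(y, abs=1e-5)

    def test_fit_invariant_to_group_label_recoding(self, grid, rng):
        x = np.concatenate([grid, grid])
        y = np.sin(x / 2) + rng.normal(0, 0.05, len(x))
        g1 = ["a"] * len(grid) + ["b"] * len(grid)
        g2 = [17] * len(grid) + [99] * len(grid)
        f1 = fit_grouped(x, y, g1, lam=1.0)
        f2 = fit_grouped(x, y, g2, lam=1.0)
        assert f1.predict(grid) == pytest.approx(f2.predict(grid), abs=1e-9)


def test_policy_defaults_and_overrides():
    assert fix_lambda_policy("weight_kg", {}) == "auto"
    assert fix_lambda_policy("testosterone", None) == ("edf", 9.0)
    assert fix_lambda_policy("log_testosterone", None) == ("edf", 9.0)
    assert fix_lambda_policy("testosterone", {"testosterone": 2.5}) == 2.5
    with pytest.raises(ValueError):
        fix_lambda_policy("weight_kg", {"weight_kg": -3.0})


def test_serialization_roundtrip(grid, rng, tmp_path):
    y = np.sin(grid) + rng.normal(0, 0.05, len(grid))
    fit = fit_grouped(np.concatenate([grid, grid]), np.concatenate([y, y + 1]),
                      ["a"] * len(grid) + ["b"] * len(grid))
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = SmoothFit.from_json(path)
    assert back.predict(grid) == pytest.approx(fit.predict(grid), abs=1e-12)
    assert back.derivative(grid) == pytest.approx(fit.derivative(grid), abs=1e-12)
    assert back.edf == pytest.approx(fit.edf)


class TestDifferenceCurve:
    @staticmethod
    def _toy_cohort(rng, n_ind, offset=0.0):
        rows = []
        for i in range(n_ind):
            ages = np.sort(rng.uniform(0, 10, 6))
            vals = np.sin(ages / 2) + offset + rng.normal(0, 0.2, 6) + rng.normal(0, 0.15)
            for a, v in zip(ages, vals):
                rows.append({"id": f"i{i}", "age_years": a, "value": v})
        return pd.DataFrame(rows)

    def test_identical_populations_band_covers_zero(self, rng):
        cm = self._toy_cohort(rng, 40)
        cf = self._toy_cohort(rng, 40)
        fm = fit_pspline(cm.age_years, cm.value)
        ff = fit_pspline(cf.age_years, cf.value)
        dc = difference_curve(fm, ff, np.linspace(0.5, 9.5, 50), cm, cf,
                              n_boot=100, seed=1)
        assert np.mean(~dc.excludes_zero) >= 0.90

    def test_true_offset_band_excludes_zero(self, rng):
        cm = self._toy_cohort(rng, 40, offset=1.0)
        cf = self._toy_cohort(rng, 40)
        fm = fit_pspline(cm.age_years, cm.value)
        ff = fit_pspline(cf.age_years, cf.value)
        dc = difference_curve(fm, ff, np.linspace(0.5, 9.5, 50), cm, cf,
                              n_boot=100, seed=2)
        assert np.mean(dc.excludes_zero) > 0.8
        assert np.all(dc.difference[10:-10] > 0)

    def test_band_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (20, 80):
            cm = self._toy_cohort(rng, n, offset=0.5)
            cf = self._toy_cohort(rng, n)
            fm = fit_pspline(cm.age_years, cm.value)
            ff = fit_pspline(cf.age_years, cf.value)
            dc = difference_curve(fm, ff, np.linspace(1, 9, 30), cm, cf,
                                  n_boot=100, seed=3)
            widths.append(np.median(dc.hi - dc.lo))
        assert widths[1] < widths[0]

    def test_too_few_bootstraps_refused(self, rng):
        c = self._toy_cohort(rng, 10)
        fit = fit_pspline(c.age_years, c.value)
        with pytest.raises(ValueError):
            difference_curve(fit, fit, np.linspace(1, 9, 10), c, c, n_boot=10)
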