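"""Synthetic cohort generator: calibration against the dense-grid landmark
oracle, simulation contracts, and reference-parameter serialization."""

import numpy as np
import pytest

from growthscale.cohort import (
    CalibrationError,
    LandmarkTargets,
    NoiseParams,
    ReferenceParams,
    calibrate_reference,
    read_reference_toml,
    simulate_cohort,
    true_landmarks,
    write_reference_toml,
)
from growthscale.curves import DoubleLogistic


class TestCalibration:
    def test_default_targets_hit_within_tolerance(self, reference, oracle):
        assert oracle.female.corrected_peak_age == pytest.approx(6.0, abs=0.05)
        assert oracle.male.corrected_peak_age == pytest.approx(8.0, abs=0.05)
        assert oracle.female.linear_lag == pytest.approx(1.0, abs=0.05)
        assert oracle.male.creatinine_peak_age - oracle.male.corrected_peak_age == (
            pytest.approx(1.5, abs=0.05))
        assert oracle.female.testosterone_rise_age == pytest.approx(4.0, abs=0.05)
        assert oracle.male.testosterone_rise_age == pytest.approx(7.0, abs=0.05)
        assert oracle.male.testosterone_decline_onset == pytest.approx(30.0, abs=0.05)
        assert oracle.female.dhea_plateau_age == pytest.approx(15.0, abs=0.05)
        assert oracle.female.igfbp3_peak_age == pytest.approx(6.0, abs=0.05)

    def test_linear_peak_precedes_corrected_peak(self, oracle):
        for sex in ("F", "M"):
            lm = oracle[sex]
            assert lm.linear_peak_age < lm.corrected_peak_age

    def test_female_creatinine_has_no_spurt(self, reference, oracle):
        assert oracle.female.creatinine_monotone
        t = np.arange(0.0, 25.0, 0.01)
        v = reference.female.creatinine.deriv(t)
        assert np.all(np.diff(v) < 0)  # velocity highest at birth, falling ever after

    def test_dhea_shared_and_testosterone_dimorphic(self, reference):
        assert reference.female.dhea == reference.male.dhea
        adult = np.array([20.0])
        assert reference.male.testosterone.value(adult) > reference.female.testosterone.value(adult)

    def test_single_logistic_velocity_peaks_at_centre(self):
        """A symmetric logistic's velocity peaks at its own centre; the
        second component is pushed far out so it cannot interfere."""
        from growthscale.cohort import _corrected_peak_analytic

        dl = DoubleLogistic(A1=100.0, r1=0.8, c1=5.0, A2=1e-6, r2=1.0, c2=40.0)
        assert _corrected_peak_analytic(dl) == pytest.approx(5.0, abs=0.01)

    def test_infeasible_targets_raise_with_residuals(self):
        bad = LandmarkTargets(female_corrected_peak=6.0, female_linear_lag=30.0)
        with pytest.raises(CalibrationError):
            calibrate_reference(bad)


class TestSimulation:
    def test_seed_determinism_and_divergence(self, reference):
        a = simulate_cohort(reference, n_per_sex=10, seed=5)
        b = simulate_cohort(reference, n_per_sex=10, seed=5)
        c = simulate_cohort(reference, n_per_sex=10, seed=6)
        assert a.equals(b)
        assert not a["value"].equals(c["value"])

    def test_noiseless_records_lie_on_reference_curves(self, noiseless_reference):
        df = simulate_cohort(noiseless_reference, n_per_sex=6, seed=2)
        p = noiseless_reference
        for sex, sp in (("F", p.female), ("M", p.male)):
            w = df[(df.sex == sex) & (df.variable == "weight_kg")]
            expected = sp.alpha * sp.size.value(w.age_years.to_numpy())
            assert w.value.to_numpy() == pytest.approx(expected, rel=1e-9)
            f = df[(df.sex == sex) & (df.variable == "forearm_cm")]
            expected = sp.size.value(f.age_years.to_numpy()) ** (1 / p.k)
            assert f.value.to_numpy() == pytest.approx(expected, rel=1e-9)
            h = df[(df.sex == sex) & (df.variable == "testosterone")]
            expected = np.exp(sp.testosterone.value(h.age_years.to_numpy()))
            assert h.value.to_numpy() == pytest.approx(expected, rel=1e-9)

    def test_noiseless_isometric_link(self, noiseless_reference):
        """weight/alpha equals length^k record by record when noise is off."""
        df = simulate_cohort(noiseless_reference, n_per_sex=4, seed=9)
        p = noiseless_reference
        for sex, sp in (("F", p.female), ("M", p.male)):
            sub = df[df.sex == sex]
            w = sub[sub.variable == "weight_kg"].set_index("age_years")["value"]
            f = sub[sub.variable == "forearm_cm"]
            # evaluate the latent curve at the forearm ages through the weight link
            s_at = sp.size.value(f.age_years.to_numpy())
            assert (sp.alpha * s_at) / sp.alpha - f.value.to_numpy() ** p.k == (
                pytest.approx(np.zeros(len(f)), abs=1e-6 * np.max(s_at)))

    def test_log_weight_residual_sd_matches_noise_setting(self, reference):
        """With random effects off, log-weight scatter about the curve is the
        configured measurement SD (0.04) within 20%."""
        p = ReferenceParams(
            k=reference.k, female=reference.female, male=reference.male,
            noise=NoiseParams(sd_size=0.0, sd_timing=0.0, sd_zoo=0.0, pregnant_prob=0.0),
        )
        df = simulate_cohort(p, n_per_sex=80, seed=3)
        w = df[(df.variable == "weight_kg") & (df.sex == "F")]
        resid = np.log(w.value.to_numpy()) - np.log(
            p.female.alpha * p.female.size.value(w.age_years.to_numpy()))
        assert np.std(resid) == pytest.approx(0.04, rel=0.2)

    def test_pregnancy_flags_and_inflation(self, reference, noiseless_reference):
        df = simulate_cohort(reference, n_per_sex=80, seed=1)
        preg = df[df.pregnant]
        assert (preg.sex == "F").all()
        assert (preg.age_years >= 8.0).all()
        w = df[(df.variable == "weight_kg") & (df.sex == "F") & (df.age_years >= 8)]
        assert 0.05 < w.pregnant.mean() < 0.15
        # inflation is exactly x1.1 in a noiseless run
        p = ReferenceParams(
            k=reference.k, female=reference.female, male=reference.male,
            noise=NoiseParams(sigma_weight=0.0, sigma_length=0.0, sigma_hormone=0.0,
                              sd_size=0.0, sd_timing=0.0, sd_zoo=0.0),
        )
        d0 = simulate_cohort(p, n_per_sex=30, seed=4)
        wp = d0[(d0.variable == "weight_kg") & d0.pregnant]
        expected = 1.1 * p.female.alpha * p.female.size.value(wp.age_years.to_numpy())
        assert wp.value.to_numpy() == pytest.approx(expected, rel=1e-9)

    def test_schema_and_ranges(self, cohort):
        assert set(cohort.columns) == {
            "id", "sex", "zoo", "age_years", "variable", "value", "pregnant", "date_index"}
        assert (cohort.value > 0).all()
        assert cohort.age_years.between(0, 55).all()
        assert set(cohort.variable.unique()) == {
            "weight_kg", "forearm_cm", "creatinine", "DHEA", "testosterone", "IGFBP3"}

    def test_rejects_invalid_inputs(self, reference):
        with pytest.raises(ValueError):
            simulate_cohort(reference, n_per_sex=0, seed=1)
        with pytest.raises(ValueError):
            NoiseParams(sigma_weight=-0.1)


def test_reference_toml_roundtrip(tmp_path, reference):
    path = tmp_path / "ref.toml"
    write_reference_toml(reference, path)
    back = read_reference_toml(path)
    a = simulate_cohort(reference, n_per_sex=4, seed=7)
    b = simulate_cohort(back, n_per_sex=4, seed=7)
    assert a.equals(b)


def test_shipped_reference_toml_matches_calibration(reference):
    from importlib.resources import files

    path = files("growthscale").joinpath("data/reference_params.toml")
    shipped = read_reference_toml(str(path))
    assert shipped.k == reference.k
    assert shipped.female.size.c2 == pytest.approx(reference.female.size.c2, abs=1e-9)
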