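"""Seeded synthetic longitudinal cohorts of zoo-housed bonobos.

The generator produces the statistical structure the analysis assumes:

* a latent per-sex size curve ``S(t)`` on the *weight dimension* (units of
  cm**k), so the scale-corrected truth is primary and the linear-length
  artifact is emergent: weight = alpha*S, forearm length = S**(1/k);
* log-scale hormone trajectories (urinary testosterone, DHEA, IGFBP-3) and
  creatinine as a lean-mass proxy;
* individual heterogeneity (log-normal size multipliers, normal timing
  shifts of the adolescent component), zoo intercepts, multiplicative
  measurement noise, and a pregnancy flag that inflates female weights;
* irregular mixed-longitudinal sampling: dense weight records, sparse
  forearm and urine visits.

Reference parameters are *calibrated* so that the noiseless curves place
their landmarks (peak-velocity ages, hormone rise/plateau ages, cross-
variable lags) at the values reported for bonobos: female/male peak growth
velocity at 6/8 y, a 1-y female linear-vs-corrected lag, a +1.5-y male
muscle (creatinine) lag, testosterone rising fastest at 4 y (F) / 7 y (M)
and declining after 30 y, and a DHEA plateau at 15 y.  Calibration is by
root-finding on the analytic curves and is always verified against the
dense-grid landmark oracle in :func:`true_landmarks`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .curves import DoubleLogistic, GaussianBump, LogisticWithDecline, SaturatingExp

__all__ = [
    "VARIABLES",
    "HORMONE_VARIABLES",
    "LandmarkTargets",
    "SexParams",
    "NoiseParams",
    "SamplingScheme",
    "ReferenceParams",
    "SexLandmarks",
    "TrueLandmarks",
    "CalibrationError",
    "calibrate_reference",
    "default_reference",
    "true_landmarks",
    "simulate_cohort",
    "write_reference_toml",
    "read_reference_toml",
]

VARIABLES = ["weight_kg", "forearm_cm", "creatinine", "DHEA", "testosterone", "IGFBP3"]
HORMONE_VARIABLES = ["creatinine", "DHEA", "testosterone", "IGFBP3"]

_GRID_STEP = 0.01  # years; landmark oracle resolution


@dataclass(frozen=True)
class OffsetDoubleLogistic:
    """base + double logistic; used for log-scale creatinine."""

    base: float
    dl: DoubleLogistic

    def value(self, t):
        return self.base + self.dl.value(t)

    def deriv(self, t):
        return self.dl.deriv(t)

    def second(self, t):
        return self.dl.second(t)


HormoneCurve = Union[LogisticWithDecline, SaturatingExp, GaussianBump, OffsetDoubleLogistic]


@dataclass(frozen=True)
class LandmarkTargets:
    """Printed landmark ages (years) that calibration must reproduce."""

    female_corrected_peak: float = 6.0
    male_corrected_peak: float = 8.0
    female_linear_lag: float = 1.0
    male_creatinine_lag: float = 1.5
    testosterone_rise_female: float = 4.0
    testosterone_rise_male: float = 7.0
    testosterone_decline_onset: float = 30.0
    dhea_plateau: float = 15.0
    creatinine_female_decline_by: float = 5.0
    igfbp3_female_peak: float | None = None  # defaults to female growth peak


@dataclass(frozen=True)
class SexParams:
    size: DoubleLogistic  # latent S(t), cm**k units
    alpha: float  # kg per unit S: weight = alpha * S
    testosterone: LogisticWithDecline  # log level
    dhea: SaturatingExp  # log level
    igfbp3: GaussianBump  # log level
    creatinine: HormoneCurve  # log level


@dataclass(frozen=True)
class NoiseParams:
    sigma_weight: float = 0.04  # log-scale measurement SDs
    sigma_length: float = 0.02
    sigma_hormone: float = 0.3
    sd_size: float = 0.08  # log-normal individual size multiplier
    sd_timing: float = 0.5  # normal shift of adolescent centre c2, years
    sd_zoo: float = 0.05  # zoo intercept, log units
    creatinine_young_factor: float = 1.5  # extra noise before age 3
    pregnant_prob: float = 0.10
    pregnant_factor: float = 1.1

    def __post_init__(self):
        for name in ("sigma_weight", "sigma_length", "sigma_hormone", "sd_size", "sd_timing", "sd_zoo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SamplingScheme:
    """Irregular mixed-longitudinal sampling, one 'career' per individual."""

    weight_interval_mean: float = 0.5  # years between weighings (exponential)
    forearm_visits: int = 5
    urine_visits: int = 5
    igfbp3_visits: int = 3  # subset of urine visits with enough volume
    min_final_age: float = 2.0
    max_final_age: float = 45.0
    duplicate_day_prob: float = 0.03  # same-day repeat weighings
    n_zoos: int = 12


@dataclass(frozen=True)
class ReferenceParams:
    k: float
    female: SexParams
    male: SexParams
    noise: NoiseParams = field(default_factory=NoiseParams)


# ---------------------------------------------------------------------------
# landmark oracle (dense grid, step 0.01 y)


@dataclass
class SexLandmarks:
    corrected_peak_age: float
    linear_peak_age: float | None
    linear_lag: float | None
    take_off_age: float
    creatinine_peak_age: float | None
    creatinine_monotone: bool
    testosterone_rise_age: float
    testosterone_plateau_age: float
    testosterone_decline_onset: float | None
    dhea_rise_age: float
    dhea_plateau_age: float
    igfbp3_peak_age: float


@dataclass
class TrueLandmarks:
    female: SexLandmarks
    male: SexLandmarks
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, sex: str) -> SexLandmarks:
        return {"F": self.female, "M": self.male}[sex]


def _grid(lo: float, hi: float, step: float = _GRID_STEP) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def _local_maxima(v: np.ndarray) -> np.ndarray:
    d = np.diff(v)
    return np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1


def _last_local_max(t: np.ndarray, v: np.ndarray, min_frac: float = 0.0) -> float | None:
    """Age of the last interior local maximum of v exceeding min_frac*max(v)."""
    idx = _local_maxima(v)
    if min_frac > 0 and len(idx):
        idx = idx[v[idx] >= min_frac * np.max(v)]
    if len(idx) == 0:
        return None
    return float(t[idx[-1]])


def _take_off_age(t: np.ndarray, v: np.ndarray, peak_age: float) -> float:
    """Last local minimum of v before the peak, else grid start."""
    before = t < peak_age
    d = np.diff(v[before])
    mins = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    if len(mins) == 0:
        return float(t[0])
    return float(t[before][mins[-1]])


def _plateau_age(t: np.ndarray, y: np.ndarray, frac: float = 0.99) -> tuple[float, bool]:
    """First age where y reaches frac of its range; flagged when the max ties."""
    rng = np.max(y) - np.min(y)
    if rng <= 0:
        return float(t[0]), True
    hit = np.where(y - np.min(y) >= frac * rng)[0]
    tie = np.count_nonzero(np.isclose(y, np.max(y), rtol=0, atol=1e-12 * max(1.0, rng))) > 1
    return float(t[hit[0]]), tie


def _decline_onset(t: np.ndarray, dy: np.ndarray, after: float) -> float | None:
    """Last nonnegative -> negative crossing of the derivative at ages >= `after`."""
    m = t >= after
    tt, d = t[m], dy[m]
    cross = np.where((d[:-1] >= 0) & (d[1:] < 0))[0]
    if len(cross) == 0:
        return None
    i = cross[-1]
    # linear interpolation of the crossing age
    if d[i] == d[i + 1]:
        return float(tt[i])
    w = d[i] / (d[i] - d[i + 1])
    return float(tt[i] + w * (tt[i + 1] - tt[i]))


def _sex_landmarks(p: SexParams, k: float, flags: list[str]) -> SexLandmarks:
    t = _grid(0.0, 25.0)
    vs = p.size.deriv(t)  # corrected-scale (weight-dimension) velocity
    i = int(np.argmax(vs))
    corrected = float(t[i])
    L = p.size.value(t) ** (1.0 / k)
    vl = np.gradient(L, t)
    linear = _last_local_max(t, vl)
    lag = corrected - linear if linear is not None else None
    take_off = _take_off_age(t, vs, corrected)

    if isinstance(p.creatinine, SaturatingExp):
        crea_peak, crea_mono = None, True
    else:
        vcrea = p.creatinine.deriv(t)
        crea_peak, crea_mono = float(t[int(np.argmax(vcrea))]), False

    th = _grid(0.0, 55.0)
    tlog = p.testosterone.value(th)
    tder = p.testosterone.deriv(th)
    t25 = th <= 25.0
    t_rise = float(th[int(np.argmax(tder[t25]))])
    t_plat, tie = _plateau_age(th[t25], tlog[t25])
    if tie:
        flags.append("testosterone plateau: tied maximum, earliest age returned")
    t_decl = _decline_onset(th, tder, after=t_plat)

    dlog = p.dhea.value(t)
    dder = p.dhea.deriv(t)
    d_rise = float(t[int(np.argmax(dder))])
    d_plat, tie = _plateau_age(t, dlog)
    if tie:
        flags.append("DHEA plateau: tied maximum, earliest age returned")

    ig = p.igfbp3.value(t)
    igf_peak = float(t[int(np.argmax(ig))])

    return SexLandmarks(
        corrected_peak_age=corrected,
        linear_peak_age=linear,
        linear_lag=lag,
        take_off_age=take_off,
        creatinine_peak_age=crea_peak,
        creatinine_monotone=crea_mono,
        testosterone_rise_age=t_rise,
        testosterone_plateau_age=t_plat,
        testosterone_decline_onset=t_decl,
        dhea_rise_age=d_rise,
        dhea_plateau_age=d_plat,
        igfbp3_peak_age=igf_peak,
    )


def true_landmarks(params: ReferenceParams) -> TrueLandmarks:
    """Dense-grid (0.01 y) landmark oracle on the noiseless reference curves."""
    flags: list[str] = []
    return TrueLandmarks(
        female=_sex_landmarks(params.female, params.k, flags),
        male=_sex_landmarks(params.male, params.k, flags),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# calibration


class CalibrationError(RuntimeError):
    """Raised when no parameters meet the landmark targets; carries residuals."""

    def __init__(self, message: str, residuals: dict[str, float]):
        super().__init__(f"{message}; residuals: {residuals}")
        self.residuals = residuals


def _corrected_peak_analytic(dl: DoubleLogistic) -> float:
    """argmax of S' via brentq on S'' around the dense-grid argmax."""
    t = _grid(0.0, 25.0)
    t0 = float(t[int(np.argmax(dl.deriv(t)))])
    lo, hi = t0 - 0.05, t0 + 0.05
    f = lambda x: float(dl.second(x))
    if f(lo) * f(hi) > 0:  # boundary max; fall back to grid value
        return t0
    return float(brentq(f, lo, hi, xtol=1e-8))


def _linear_spurt_peak_analytic(dl: DoubleLogistic, k: float) -> float | None:
    """Last interior local max of d(S**1/k)/dt, refined by root-finding.

    Roots of (1/k - 1)*S'**2 + S*S'' = 0 are the critical ages of the
    linear-scale velocity.
    """
    t = _grid(0.0, 25.0)
    L = dl.value(t) ** (1.0 / k)
    vl = np.gradient(L, t)
    age = _last_local_max(t, vl)
    if age is None:
        return None
    g = lambda x: float((1.0 / k - 1.0) * dl.deriv(x) ** 2 + dl.value(x) * dl.second(x))
    lo, hi = age - 0.05, age + 0.05
    if g(lo) * g(hi) > 0:
        return age
    return float(brentq(g, lo, hi, xtol=1e-8))


def _calibrate_female_size(targets: LandmarkTargets, k: float) -> DoubleLogistic:
    adult = 26.0**k  # adult forearm 26 cm on the weight dimension
    A1 = A2 = adult / 2.0
    r1, c1 = 0.45, 1.5

    def make(x):
        return DoubleLogistic(A1=A1, r1=r1, c1=c1, A2=A2, r2=x[0], c2=x[1])

    def resid(x):
        dl = make(x)
        corr = _corrected_peak_analytic(dl)
        lin = _linear_spurt_peak_analytic(dl, k)
        if lin is None:
            return [corr - targets.female_corrected_peak, 5.0]
        return [
            corr - targets.female_corrected_peak,
            lin - (targets.female_corrected_peak - targets.female_linear_lag),
        ]

    sol = least_squares(resid, x0=[0.7, targets.female_corrected_peak + 0.4],
                        bounds=([0.2, 2.0], [3.0, 15.0]), xtol=1e-12, ftol=1e-12)
    if np.max(np.abs(sol.fun)) > 0.02:
        raise CalibrationError(
            "female size curve infeasible",
            {"corrected_peak": sol.fun[0], "linear_peak": sol.fun[1]},
        )
    return make(sol.x)


def _calibrate_male_size(targets: LandmarkTargets, k: float) -> DoubleLogistic:
    adult = 27.5**k  # adult forearm 27.5 cm; longer, more pronounced spurt
    A1, A2 = adult * 0.45, adult * 0.55
    r1, c1, r2 = 0.45, 1.5, 0.9

    def make(c2):
        return DoubleLogistic(A1=A1, r1=r1, c1=c1, A2=A2, r2=r2, c2=c2)

    f = lambda c2: _corrected_peak_analytic(make(c2)) - targets.male_corrected_peak
    try:
        c2 = brentq(f, 4.0, 15.0, xtol=1e-8)
    except ValueError as exc:
        raise CalibrationError("male size curve infeasible", {"corrected_peak": float("nan")}) from exc
    return make(c2)


def _calibrate_male_creatinine(targets: LandmarkTargets) -> OffsetDoubleLogistic:
    # log-scale: childhood rise plus a muscle spurt whose velocity peak lands
    # male_creatinine_lag years after the male growth peak
    target = targets.male_corrected_peak + targets.male_creatinine_lag
    a1, r1, c1, a2, r2 = 0.9, 0.45, 1.5, 0.7, 0.9

    def make(c2):
        return DoubleLogistic(A1=a1, r1=r1, c1=c1, A2=a2, r2=r2, c2=c2)

    f = lambda c2: _corrected_peak_analytic(make(c2)) - target
    try:
        c2 = brentq(f, 4.0, 18.0, xtol=1e-8)
    except ValueError as exc:
        raise CalibrationError("male creatinine curve infeasible", {"creatinine_peak": float("nan")}) from exc
    return OffsetDoubleLogistic(base=-0.5, dl=make(c2))


def _calibrate_dhea(targets: LandmarkTargets) -> SaturatingExp:
    # first age at 99% of the range on [0, 25] equals the plateau target
    def plateau(tau):
        top = 1.0 - math.exp(-25.0 / tau)
        return -tau * math.log(1.0 - 0.99 * top)

    f = lambda tau: plateau(tau) - targets.dhea_plateau
    try:
        tau = brentq(f, 0.5, 8.0, xtol=1e-10)
    except ValueError as exc:
        raise CalibrationError("DHEA plateau infeasible", {"dhea_plateau": float("nan")}) from exc
    return SaturatingExp(base=1.0, amp=2.0, tau=tau)


def calibrate_reference(
    targets: LandmarkTargets | None = None, k: float = 2.5
) -> ReferenceParams:
    """Solve for generator parameters that hit the landmark target table.

    Nested root-finding / least squares on the analytic curves; the result
    is verified against the :func:`true_landmarks` dense-grid oracle to
    within 0.05 y and a :class:`CalibrationError` with the residual table
    is raised otherwise.
    """
    targets = targets or LandmarkTargets()
    size_f = _calibrate_female_size(targets, k)
    size_m = _calibrate_male_size(targets, k)
    dhea = _calibrate_dhea(targets)
    crea_m = _calibrate_male_creatinine(targets)
    crea_f = SaturatingExp(base=-0.5, amp=1.2, tau=2.5)
    igf_peak_f = (
        targets.igfbp3_female_peak
        if targets.igfbp3_female_peak is not None
        else targets.female_corrected_peak
    )
    female = SexParams(
        size=size_f,
        alpha=33.0 / 26.0**k,  # adult female ~33 kg
        testosterone=LogisticWithDecline(
            base=0.0, amp=1.6, r=1.8, c=targets.testosterone_rise_female,
            decline=0.004, t_dec=targets.testosterone_decline_onset,
        ),
        dhea=dhea,
        igfbp3=GaussianBump(base=2.0, amp=1.0, mu=igf_peak_f, width=3.0),
        creatinine=crea_f,
    )
    male = SexParams(
        size=size_m,
        alpha=39.0 / 27.5**k,  # adult male ~39 kg
        testosterone=LogisticWithDecline(
            base=0.0, amp=2.4, r=1.8, c=targets.testosterone_rise_male,
            decline=0.004, t_dec=targets.testosterone_decline_onset,
        ),
        dhea=dhea,  # identical across sexes by design
        igfbp3=GaussianBump(
            base=2.0, amp=1.0,
            mu=targets.male_corrected_peak + targets.male_creatinine_lag,
            width=3.5,
        ),
        creatinine=crea_m,
    )
    params = ReferenceParams(k=k, female=female, male=male)
    _verify_calibration(params, targets)
    return params


def _verify_calibration(params: ReferenceParams, targets: LandmarkTargets, tol: float = 0.05) -> None:
    lm = true_landmarks(params)
    resid = {
        "female_corrected_peak": lm.female.corrected_peak_age - targets.female_corrected_peak,
        "male_corrected_peak": lm.male.corrected_peak_age - targets.male_corrected_peak,
        "female_linear_lag": (lm.female.linear_lag or np.nan) - targets.female_linear_lag,
        "male_creatinine_lag": (lm.male.creatinine_peak_age or np.nan)
        - lm.male.corrected_peak_age
        - targets.male_creatinine_lag,
        "testosterone_rise_female": lm.female.testosterone_rise_age - targets.testosterone_rise_female,
        "testosterone_rise_male": lm.male.testosterone_rise_age - targets.testosterone_rise_male,
        "testosterone_decline_onset": (lm.male.testosterone_decline_onset or np.nan)
        - targets.testosterone_decline_onset,
        "dhea_plateau": lm.female.dhea_plateau_age - targets.dhea_plateau,
        "igfbp3_female_peak": lm.female.igfbp3_peak_age
        - (targets.igfbp3_female_peak or targets.female_corrected_peak),
    }
    bad = {k_: float(v) for k_, v in resid.items() if not np.isfinite(v) or abs(v) > tol}
    if bad:
        raise CalibrationError("calibration failed oracle verification", bad)
    if not lm.female.creatinine_monotone:
        raise CalibrationError("female creatinine must have no velocity peak", {})
    t = _grid(0.0, 25.0)
    v = params.female.creatinine.deriv(t)
    if not np.all(np.diff(v) < 0):
        raise CalibrationError("female creatinine velocity must decrease from birth", {})


_DEFAULT_CACHE: dict[float, ReferenceParams] = {}


def default_reference(k: float = 2.5) -> ReferenceParams:
    """Calibrated default parameters (cached per k)."""
    if k not in _DEFAULT_CACHE:
        _DEFAULT_CACHE[k] = calibrate_reference(LandmarkTargets(), k=k)
    return _DEFAULT_CACHE[k]


# ---------------------------------------------------------------------------
# simulation


def _individual_curve(base: DoubleLogistic, mult: float, shift: float) -> DoubleLogistic:
    return replace(base, A1=base.A1 * mult, A2=base.A2 * mult, c2=base.c2 + shift)


def simulate_cohort(
    params: ReferenceParams | None = None,
    n_per_sex: int = 80,
    seed: int = 0,
    scheme: SamplingScheme | None = None,
) -> pd.DataFrame:
    """Simulate a tidy longitudinal cohort.

    Returns a DataFrame with columns
    ``id, sex, zoo, age_years, variable, value, pregnant, date_index``.
    Reproducible: a fixed seed yields an identical frame.
    """
    if n_per_sex < 1:
        raise ValueError("n_per_sex must be >= 1")
    params = params or default_reference()
    scheme = scheme or SamplingScheme()
    noise = params.noise
    rng = np.random.default_rng(seed)
    zoo_fx = rng.normal(0.0, noise.sd_zoo, size=scheme.n_zoos)
    rows: list[tuple] = []

    for sex, sp in (("F", params.female), ("M", params.male)):
        for i in range(n_per_sex):
            ind = f"{sex}{i + 1:03d}"
            zoo = int(rng.integers(0, scheme.n_zoos))
            z = zoo_fx[zoo]
            mult = math.exp(rng.normal(0.0, noise.sd_size))
            shift = rng.normal(0.0, noise.sd_timing)
            size_i = _individual_curve(sp.size, mult, shift)
            final_age = rng.uniform(scheme.min_final_age, scheme.max_final_age)
            birth_offset = int(rng.integers(0, 20000))

            def emit(var, age, value, pregnant):
                rows.append(
                    (ind, sex, f"zoo{zoo:02d}", float(age), var,
                     float(value), bool(pregnant), birth_offset + int(round(age * 365.25)))
                )

            # --- body weight: dense irregular records from infancy on
            # (ages rounded up front so records are exact curve evaluations)
            ages = []
            a = rng.uniform(0.02, 0.2)
            while a < final_age:
                ages.append(round(a, 4))
                if rng.uniform() < scheme.duplicate_day_prob:
                    ages.append(round(a, 4))  # same-day repeat
                a += rng.exponential(scheme.weight_interval_mean)
            for a in ages:
                preg = bool(sex == "F" and a >= 8.0 and rng.uniform() < noise.pregnant_prob)
                w = sp.alpha * size_i.value(a) * math.exp(z + rng.normal(0.0, noise.sigma_weight))
                if preg:
                    w *= noise.pregnant_factor
                emit("weight_kg", a, w, preg)

            # --- forearm length: few visits, unaffected by pregnancy
            for a in np.round(np.sort(rng.uniform(0.5, final_age, size=scheme.forearm_visits)), 4):
                preg = bool(sex == "F" and a >= 8.0 and rng.uniform() < noise.pregnant_prob)
                L = size_i.value(a) ** (1.0 / params.k) * math.exp(
                    z + rng.normal(0.0, noise.sigma_length)
                )
                emit("forearm_cm", a, L, preg)

            # --- urine markers: shared visit ages
            urine_ages = np.round(np.sort(rng.uniform(0.5, final_age, size=scheme.urine_visits)), 4)
            igf_idx = set(
                rng.choice(scheme.urine_visits, size=min(scheme.igfbp3_visits, scheme.urine_visits),
                           replace=False)
            )
            for j, a in enumerate(urine_ages):
                preg = bool(sex == "F" and a >= 8.0 and rng.uniform() < noise.pregnant_prob)
                sd_crea = noise.sigma_hormone * (noise.creatinine_young_factor if a < 3 else 1.0)
                emit("creatinine", a, math.exp(sp.creatinine.value(a) + z + rng.normal(0.0, sd_crea)), preg)
                emit("DHEA", a, math.exp(sp.dhea.value(a) + z + rng.normal(0.0, noise.sigma_hormone)), preg)
                emit("testosterone", a, math.exp(sp.testosterone.value(a) + z + rng.normal(0.0, noise.sigma_hormone)), preg)
                if j in igf_idx:
                    emit("IGFBP3", a, math.exp(sp.igfbp3.value(a) + z + rng.normal(0.0, noise.sigma_hormone)), preg)

    return pd.DataFrame(
        rows,
        columns=["id", "sex", "zoo", "age_years", "variable", "value", "pregnant", "date_index"],
    )


# ---------------------------------------------------------------------------
# TOML serialization of reference parameter sets


def _curve_to_dict(curve) -> dict:
    if isinstance(curve, DoubleLogistic):
        return {"family": "double_logistic", "A1": curve.A1, "r1": curve.r1,
                "c1": curve.c1, "A2": curve.A2, "r2": curve.r2, "c2": curve.c2}
    if isinstance(curve, OffsetDoubleLogistic):
        d = _curve_to_dict(curve.dl)
        d.update(family="offset_double_logistic", base=curve.base)
        return d
    if isinstance(curve, LogisticWithDecline):
        return {"family": "logistic_with_decline", "base": curve.base, "amp": curve.amp,
                "r": curve.r, "c": curve.c, "decline": curve.decline, "t_dec": curve.t_dec}
    if isinstance(curve, SaturatingExp):
        return {"family": "saturating_exp", "base": curve.base, "amp": curve.amp, "tau": curve.tau}
    if isinstance(curve, GaussianBump):
        return {"family": "gaussian_bump", "base": curve.base, "amp": curve.amp,
                "mu": curve.mu, "width": curve.width}
    raise TypeError(type(curve))


def _curve_from_dict(d: dict):
    fam = d["family"]
    if fam == "double_logistic":
        return DoubleLogistic(A1=d["A1"], r1=d["r1"], c1=d["c1"], A2=d["A2"], r2=d["r2"], c2=d["c2"])
    if fam == "offset_double_logistic":
        return OffsetDoubleLogistic(base=d["base"], dl=DoubleLogistic(
            A1=d["A1"], r1=d["r1"], c1=d["c1"], A2=d["A2"], r2=d["r2"], c2=d["c2"]))
    if fam == "logistic_with_decline":
        return LogisticWithDecline(base=d["base"], amp=d["amp"], r=d["r"], c=d["c"],
                                   decline=d["decline"], t_dec=d["t_dec"])
    if fam == "saturating_exp":
        return SaturatingExp(base=d["base"], amp=d["amp"], tau=d["tau"])
    if fam == "gaussian_bump":
        return GaussianBump(base=d["base"], amp=d["amp"], mu=d["mu"], width=d["width"])
    raise ValueError(f"unknown curve family {fam!r}")


_SECTIONS = {
    "REF-F": lambda p: _curve_to_dict(p.female.size) | {"alpha": p.female.alpha},
    "REF-M": lambda p: _curve_to_dict(p.male.size) | {"alpha": p.male.alpha},
    "REF-T-F": lambda p: _curve_to_dict(p.female.testosterone),
    "REF-T-M": lambda p: _curve_to_dict(p.male.testosterone),
    "REF-DHEA": lambda p: _curve_to_dict(p.female.dhea),
    "REF-IGFBP3": lambda p: _curve_to_dict(p.female.igfbp3) | {
        "mu_male": p.male.igfbp3.mu, "width_male": p.male.igfbp3.width,
        "amp_male": p.male.igfbp3.amp, "base_male": p.male.igfbp3.base},
    "REF-CREA-F": lambda p: _curve_to_dict(p.female.creatinine),
    "REF-CREA-M": lambda p: _curve_to_dict(p.male.creatinine),
}


def _toml_value(v):
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    v = float(v)
    if math.isinf(v):
        return "inf"
    return repr(v)


def write_reference_toml(params: ReferenceParams, path) -> None:
    lines = ["[meta]", f"k = {params.k!r}", ""]
    for name, fn in _SECTIONS.items():
        lines.append(f'["{name}"]')
        for key, val in fn(params).items():
            lines.append(f"{key} = {_toml_value(val)}")
        lines.append("")
    lines.append("[noise]")
    for key, val in vars(params.noise).items():
        lines.append(f"{key} = {_toml_value(val)}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_reference_toml(path) -> ReferenceParams:
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    k = doc["meta"]["k"]
    igf = doc["REF-IGFBP3"]
    female = SexParams(
        size=_curve_from_dict(doc["REF-F"]),
        alpha=doc["REF-F"]["alpha"],
        testosterone=_curve_from_dict(doc["REF-T-F"]),
        dhea=_curve_from_dict(doc["REF-DHEA"]),
        igfbp3=_curve_from_dict(igf),
        creatinine=_curve_from_dict(doc["REF-CREA-F"]),
    )
    male = SexParams(
        size=_curve_from_dict(doc["REF-M"]),
        alpha=doc["REF-M"]["alpha"],
        testosterone=_curve_from_dict(doc["REF-T-M"]),
        dhea=_curve_from_dict(doc["REF-DHEA"]),
        igfbp3=GaussianBump(base=igf["base_male"], amp=igf["amp_male"],
                            mu=igf["mu_male"], width=igf["width_male"]),
        creatinine=_curve_from_dict(doc["REF-CREA-M"]),
    )
    noise = NoiseParams(**doc["noise"])
    return ReferenceParams(k=k, female=female, male=male, noise=noise)
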