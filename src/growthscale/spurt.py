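"""Scale-correction transforms and growth-spurt landmark detection.

A growth spurt is landmarked on the fitted velocity curve (first
derivative of a smoothed size-for-age trajectory): take-off (last local
minimum of velocity before the peak), age at peak velocity, peak velocity,
and cessation.  Because infant growth velocity on the linear-length scale
exceeds the adolescent bump (the very scaling artifact this package is
about), the peak is taken as the *last* substantial interior local maximum
of the velocity curve rather than its global argmax; for single-peaked
curves the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .smoothing import SmoothFit, fit_pspline

__all__ = [
    "DIMENSION_TAGS",
    "transform_dimension",
    "VelocityCurve",
    "velocity_curve",
    "SpurtSummary",
    "detect_spurt",
    "peak_alignment",
    "bootstrap_peak_age",
    "HormoneLandmarks",
    "hormone_landmarks",
]

DIMENSION_TAGS = ("length_linear", "length_corrected", "weight", "weight_downscaled")

# exponent applied to a positive value when moving from -> to
_TRANSFORMS = {
    ("length_linear", "length_corrected"): lambda k: k,
    ("length_corrected", "length_linear"): lambda k: 1.0 / k,
    ("weight", "weight_downscaled"): lambda k: 1.0 / k,
    ("weight_downscaled", "weight"): lambda k: k,
}


def transform_dimension(values, from_tag: str, to_tag: str, k: float = 2.5) -> np.ndarray:
    """Move positive measurements between the linear and volume dimensions.

    length -> corrected raises to k (cm to cm**k); weight -> downscaled
    raises to 1/k (kg to kg**(1/k)).  Bijective on positive values.
    """
    for tag in (from_tag, to_tag):
        if tag not in DIMENSION_TAGS:
            raise ValueError(f"unknown dimension tag {tag!r}")
    if not 2.0 <= k <= 3.0:
        raise ValueError("k must lie in [2, 3]")
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("dimension transforms require positive values")
    if from_tag == to_tag:
        return values.copy()
    try:
        expo = _TRANSFORMS[(from_tag, to_tag)](k)
    except KeyError:
        raise ValueError(f"no transform from {from_tag!r} to {to_tag!r}") from None
    return values**expo


@dataclass
class VelocityCurve:
    """First derivative of a fitted trajectory on a regular age grid."""

    ages: np.ndarray
    velocity: np.ndarray
    dimension: str | None = None
    variable: str | None = None
    sex: str | None = None


def velocity_curve(
    fit: SmoothFit,
    grid_step: float = 0.1,
    dimension: str | None = None,
    variable: str | None = None,
    sex: str | None = None,
    age_range: tuple[float, float] | None = None,
) -> VelocityCurve:
    """Velocity on a regular grid over (a sub-range of) the fitted range."""
    lo, hi = fit.age_range
    if age_range is not None:
        rlo, rhi = age_range
        if rlo < lo - 1e-9 or rhi > hi + 1e-9:
            raise ValueError("requested grid outside fitted range")
        lo, hi = max(lo, rlo), min(hi, rhi)
    ages = np.arange(lo, hi + grid_step / 2, grid_step)
    ages = np.clip(ages, *fit.age_range)
    return VelocityCurve(
        ages=ages, velocity=fit.derivative(ages),
        dimension=dimension, variable=variable, sex=sex,
    )


@dataclass
class SpurtSummary:
    take_off_age: float | None
    peak_age: float | None
    peak_velocity: float | None
    cessation_age: float | None
    detected: bool
    dimension: str | None = None
    variable: str | None = None
    sex: str | None = None
    boundary_peak: bool = False
    tied_peak: bool = False

    def __post_init__(self):
        seq = [a for a in (self.take_off_age, self.peak_age, self.cessation_age) if a is not None]
        if self.detected and seq != sorted(seq):
            raise ValueError("landmarks must be ordered take_off < peak < cessation")


def detect_spurt(
    v: VelocityCurve,
    min_rel_rise: float = 0.10,
    min_peak_frac: float = 0.5,
) -> SpurtSummary:
    """Landmark a growth spurt on a velocity curve.

    peak_age: last interior local maximum of v among candidates with
    velocity >= ``min_peak_frac`` of the grid maximum (argmax for a
    single-peaked curve).  take_off_age: last local minimum before the
    peak, else grid start.  detected requires an interior peak and a
    relative rise ``(v_peak - v_takeoff)/v_takeoff >= min_rel_rise``.
    cessation_age: first age after the peak where v falls back below the
    take-off velocity (None if it never does).
    """
    t, vel = np.asarray(v.ages, float), np.asarray(v.velocity, float)
    if len(t) < 10:
        raise ValueError("need at least 10 grid points")
    meta = dict(dimension=v.dimension, variable=v.variable, sex=v.sex)

    if np.allclose(vel, vel[0]):
        return SpurtSummary(None, None, None, None, detected=False, **meta)

    d = np.diff(vel)
    lmax = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    if min_peak_frac > 0 and len(lmax):
        lmax = lmax[vel[lmax] >= min_peak_frac * np.max(vel)]
    if len(lmax) == 0:
        i = int(np.argmax(vel))
        return SpurtSummary(
            None, float(t[i]), float(vel[i]), None, detected=False,
            boundary_peak=True, **meta,
        )
    ip = int(lmax[-1])
    tied = bool(np.count_nonzero(np.isclose(vel[lmax], vel[ip], rtol=1e-12, atol=0)) > 1)
    if tied:
        ip = int(lmax[np.isclose(vel[lmax], vel[ip], rtol=1e-12, atol=0)][0])
    peak_age, peak_vel = float(t[ip]), float(vel[ip])

    before = d[: max(ip - 1, 0)]
    lmin = np.where((before[:-1] < 0) & (before[1:] >= 0))[0] + 1 if len(before) > 1 else np.array([], int)
    it = int(lmin[-1]) if len(lmin) else 0
    take_off_age, take_off_vel = float(t[it]), float(vel[it])

    if take_off_vel > 0:
        rise = (peak_vel - take_off_vel) / take_off_vel
    else:
        rise = np.inf if peak_vel > 0 else 0.0
    detected = bool(rise >= min_rel_rise)

    cessation = None
    after = np.where((t > peak_age) & (vel < take_off_vel))[0]
    if len(after):
        cessation = float(t[after[0]])
    if not detected:
        return SpurtSummary(None, peak_age, peak_vel, None, detected=False,
                            tied_peak=tied, **meta)
    return SpurtSummary(take_off_age, peak_age, peak_vel, cessation, detected=True,
                        tied_peak=tied, **meta)


def peak_alignment(summaries: list[SpurtSummary]) -> pd.DataFrame:
    """Pairwise peak-age differences between detected spurts sharing a sex.

    Rows: sex, variable/dimension of each member, peak ages, and the
    difference (second minus first).  Undetected spurts are excluded with
    a warning.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two spurt summaries")
    usable = []
    for s in summaries:
        if s.detected:
            usable.append(s)
        else:
            warnings.warn(
                f"excluding undetected spurt ({s.sex}, {s.variable}, {s.dimension})",
                stacklevel=2,
            )
    rows = []
    by_sex: dict = {}
    for s in usable:
        by_sex.setdefault(s.sex, []).append(s)
    for sex, group in by_sex.items():
        for s1, s2 in combinations(group, 2):
            rows.append(
                {
                    "sex": sex,
                    "first": f"{s1.variable}:{s1.dimension}",
                    "second": f"{s2.variable}:{s2.dimension}",
                    "peak_age_first": s1.peak_age,
                    "peak_age_second": s2.peak_age,
                    "difference": s2.peak_age - s1.peak_age,
                }
            )
    return pd.DataFrame(rows, columns=["sex", "first", "second",
                                       "peak_age_first", "peak_age_second", "difference"])


def bootstrap_peak_age(
    cohort: pd.DataFrame,
    fit: SmoothFit,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    grid_step: float = 0.1,
    age_range: tuple[float, float] | None = None,
    log_response: bool = False,
) -> tuple[float, float]:
    """Cluster-bootstrap percentile CI for the spurt peak age.

    ``cohort`` needs columns id, age_years, value (one variable, one sex);
    individuals are resampled with replacement and the smooth refitted at
    the original smoothing parameter.  With ``log_response`` the fit is on
    log values and the peak is taken on the back-transformed velocity
    ``exp(f) * f'`` — the response-scale peak, not the log-scale one.
    """
    rng = np.random.default_rng(seed)
    clusters = [g[["age_years", "value"]].to_numpy() for _, g in cohort.groupby("id")]
    peaks = []
    for _ in range(n_boot):
        take = rng.integers(0, len(clusters), size=len(clusters))
        arr = np.vstack([clusters[i] for i in take])
        try:
            fb = fit_pspline(arr[:, 0], arr[:, 1], spec=fit.spec, lam=fit.lam)
        except ValueError:
            continue
        rng_lo, rng_hi = fb.age_range
        if age_range is not None:
            rng_lo, rng_hi = max(rng_lo, age_range[0]), min(rng_hi, age_range[1])
        if rng_hi <= rng_lo:
            continue
        vb = velocity_curve(fb, grid_step=grid_step, age_range=(rng_lo, rng_hi))
        if log_response:
            vb.velocity = np.exp(fb.predict(vb.ages)) * vb.velocity
        # interior argmax: on the analysis dimension the spurt is the
        # global velocity maximum, and argmax does not chase tail wiggles
        i = int(np.argmax(vb.velocity))
        if 0 < i < len(vb.ages) - 1:
            peaks.append(float(vb.ages[i]))
    if len(peaks) < max(20, n_boot // 4):
        raise RuntimeError("too few successful bootstrap replicates for a peak-age CI")
    a = (1 - level) / 2
    return float(np.quantile(peaks, a)), float(np.quantile(peaks, 1 - a))


@dataclass
class HormoneLandmarks:
    rise_fastest_age: float | None
    plateau_age: float | None
    decline_onset_age: float | None
    flat: bool = False


def hormone_landmarks(
    fit: SmoothFit,
    grid_step: float = 0.01,
    plateau_frac: float = 0.99,
    flat_tol: float = 1e-8,
) -> HormoneLandmarks:
    """Landmarks of a fitted log-hormone trajectory.

    rise-fastest: argmax of the first derivative; plateau: first age where
    the level reaches ``plateau_frac`` of its fitted range; decline onset:
    last nonnegative-to-negative crossing of the derivative after the
    plateau (None for monotone curves).
    """
    lo, hi = fit.age_range
    t = np.clip(np.arange(lo, hi + grid_step / 2, grid_step), lo, hi)
    y = fit.predict(t)
    dy = fit.derivative(t)
    if np.max(np.abs(dy)) < flat_tol or np.max(y) - np.min(y) < flat_tol:
        return HormoneLandmarks(None, None, None, flat=True)
    rise = float(t[int(np.argmax(dy))])
    rngy = np.max(y) - np.min(y)
    plateau = float(t[np.where(y - np.min(y) >= plateau_frac * rngy)[0][0]])
    after = t >= plateau
    dcut = dy[after]
    ycut = y[after]
    tcut = t[after]
    cross = np.where((dcut[:-1] >= 0) & (dcut[1:] < 0))[0]
    decline = None
    for i in cross[::-1]:
        # a genuine decline loses a material part of the fitted range after
        # the crossing; spline micro-wiggles on a flat plateau do not
        if ycut[i] - np.min(ycut[i:]) < 0.01 * rngy:
            continue
        w = 0.0 if dcut[i] == dcut[i + 1] else dcut[i] / (dcut[i] - dcut[i + 1])
        decline = float(tcut[i] + w * (tcut[i + 1] - tcut[i]))
        break
    return HormoneLandmarks(rise, plateau, decline)
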