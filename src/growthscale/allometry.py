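"""Weight-length scaling-exponent estimation on the log-log scale.

If weight W and a linear dimension L are tied by the power law
``W = alpha * L**k``, then ``log W = log alpha + k * log L`` and the
exponent is the slope of a log-log regression.  Ordinary least squares
with weight as the response is the default (weight is the noisier
measure); the standardized major axis (SMA) slope, preferred in much of
the allometry literature when both variables carry error, is also
reported.  A quadratic log-log term is fitted alongside as a curvature
diagnostic: a single power law is adequate when its CI covers zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AllometryFit", "fit_loglog", "IsometryDecision", "check_isometry", "match_pairs"]


@dataclass(frozen=True)
class AllometryFit:
    exponent: float  # k-hat: slope of log W on log L
    intercept: float  # log alpha-hat
    se: float
    ci: tuple[float, float]
    r_squared: float
    method: str  # "OLS" | "SMA"
    n: int
    curvature: float
    curvature_ci: tuple[float, float]


def fit_loglog(weights, lengths, method: str = "OLS", level: float = 0.95) -> AllometryFit:
    """Estimate the scaling exponent from paired weight/length observations."""
    w = np.asarray(weights, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if w.shape != l.shape or w.ndim != 1:
        raise ValueError("weights and lengths must be matching 1-D arrays")
    if len(w) < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("weights and lengths must be positive")
    x, y = np.log(l), np.log(w)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log length")
    n = len(x)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    tq = stats.t.ppf(0.5 + level / 2, n - 2)

    if method.upper() == "OLS":
        slope, se = res.slope, res.stderr
        ci = (slope - tq * se, slope + tq * se)
        intercept = res.intercept
    elif method.upper() == "SMA":
        # SMA slope = OLS slope / |r|; CI per Warton et al. (2006)
        r = res.rvalue
        if r == 0:
            raise ValueError("SMA slope undefined at zero correlation")
        slope = np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1)
        B = tq**2 * (1 - r2) / (n - 2)
        ci = (slope * (np.sqrt(B + 1) - np.sqrt(B)), slope * (np.sqrt(B + 1) + np.sqrt(B)))
        se = abs(slope) * np.sqrt((1 - r2) / (n - 2))
        intercept = float(np.mean(y) - slope * np.mean(x))
    else:
        raise ValueError("method must be 'OLS' or 'SMA'")

    # curvature diagnostic: quadratic term of y ~ x + x^2 (centred x)
    xc = x - np.mean(x)
    X = np.column_stack([np.ones(n), xc, xc**2])
    beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 3
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se_q = float(np.sqrt(cov[2, 2]))
        tq3 = stats.t.ppf(0.5 + level / 2, dof)
        curv_ci = (beta[2] - tq3 * se_q, beta[2] + tq3 * se_q)
    else:
        curv_ci = (-np.inf, np.inf)
    return AllometryFit(
        exponent=float(slope), intercept=float(intercept), se=float(se),
        ci=(float(ci[0]), float(ci[1])), r_squared=float(r2),
        method=method.upper(), n=n, curvature=float(beta[2]),
        curvature_ci=(float(curv_ci[0]), float(curv_ci[1])),
    )


@dataclass(frozen=True)
class IsometryDecision:
    k0: float
    k0_in_ci: bool
    curvature_zero_in_ci: bool
    exponent: float
    ci: tuple[float, float]


def check_isometry(fit: AllometryFit, k0: float) -> IsometryDecision:
    """Is a hypothesized exponent consistent with the fit, and is one power law enough?"""
    return IsometryDecision(
        k0=k0,
        k0_in_ci=bool(fit.ci[0] <= k0 <= fit.ci[1]),
        curvature_zero_in_ci=bool(fit.curvature_ci[0] <= 0 <= fit.curvature_ci[1]),
        exponent=fit.exponent,
        ci=fit.ci,
    )


def match_pairs(
    cohort: pd.DataFrame,
    weight_var: str = "weight_kg",
    length_var: str = "forearm_cm",
    window: float = 0.25,
) -> pd.DataFrame:
    """Pair same-individual weight and length records within an age window.

    Weight and length come from different sampling events, so each length
    record is matched to the nearest-in-age weight record of the same
    individual, kept only when the gap is <= ``window`` years.  Returns a
    frame with columns id, age_years, weight, length.
    """
    rows = []
    wdf = cohort[cohort["variable"] == weight_var]
    ldf = cohort[cohort["variable"] == length_var]
    for ind, lg in ldf.groupby("id"):
        wg = wdf[wdf["id"] == ind]
        if wg.empty:
            continue
        wa = wg["age_years"].to_numpy()
        wv = wg["value"].to_numpy()
        for _, rec in lg.iterrows():
            i = int(np.argmin(np.abs(wa - rec["age_years"])))
            if abs(wa[i] - rec["age_years"]) <= window:
                rows.append(
                    {"id": ind, "age_years": rec["age_years"],
                     "weight": wv[i], "length": rec["value"]}
                )
    return pd.DataFrame(rows, columns=["id", "age_years", "weight", "length"])
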