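"""Analytic latent trajectory families for the cohort generator.

Each curve exposes ``value``, ``deriv`` and ``second`` as exact closed
forms so landmark calibration can use root-finding instead of grids.  Size
curves live on the weight (volume) dimension; hormone curves live on the
natural-log concentration scale, matching how the measured markers are
modelled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DoubleLogistic", "LogisticWithDecline", "SaturatingExp", "GaussianBump"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class DoubleLogistic:
    """Sum of two logistic components: infancy/childhood plus adolescent spurt.

    S(t) = A1*sig(r1*(t-c1)) + A2*sig(r2*(t-c2)), with c1 < c2.  Amplitudes
    carry the units of the modelled dimension; rates are 1/years.
    """

    A1: float
    r1: float
    c1: float
    A2: float
    r2: float
    c2: float

    def __post_init__(self):
        if min(self.A1, self.A2, self.r1, self.r2) <= 0:
            raise ValueError("amplitudes and rates must be > 0")
        if not self.c1 < self.c2:
            raise ValueError("component centres must satisfy c1 < c2")

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return self.A1 * _sigmoid(self.r1 * (t - self.c1)) + self.A2 * _sigmoid(
            self.r2 * (t - self.c2)
        )

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        s1 = _sigmoid(self.r1 * (t - self.c1))
        s2 = _sigmoid(self.r2 * (t - self.c2))
        return self.A1 * self.r1 * s1 * (1 - s1) + self.A2 * self.r2 * s2 * (1 - s2)

    def second(self, t):
        t = np.asarray(t, dtype=float)
        s1 = _sigmoid(self.r1 * (t - self.c1))
        s2 = _sigmoid(self.r2 * (t - self.c2))
        return self.A1 * self.r1**2 * s1 * (1 - s1) * (1 - 2 * s1) + (
            self.A2 * self.r2**2 * s2 * (1 - s2) * (1 - 2 * s2)
        )


@dataclass(frozen=True)
class LogisticWithDecline:
    """Logistic rise with a smooth senescent down-ramp (log-concentration scale).

    f(t) = base + amp*sig(r*(t-c)) - decline*((t-t_dec)_+)**2 / 2.

    The quadratic hinge is C1-smooth and exactly zero before ``t_dec``, so
    the derivative's +/- zero crossing (the decline onset landmark) sits at
    ``t_dec`` up to the vanishing tail of the logistic term.
    """

    base: float
    amp: float
    r: float
    c: float
    decline: float = 0.0
    t_dec: float = np.inf

    def value(self, t):
        t = np.asarray(t, dtype=float)
        hinge = np.clip(t - self.t_dec, 0.0, None)
        return self.base + self.amp * _sigmoid(self.r * (t - self.c)) - 0.5 * self.decline * hinge**2

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        s = _sigmoid(self.r * (t - self.c))
        hinge = np.clip(t - self.t_dec, 0.0, None)
        return self.amp * self.r * s * (1 - s) - self.decline * hinge

    def second(self, t):
        t = np.asarray(t, dtype=float)
        s = _sigmoid(self.r * (t - self.c))
        step = np.where(t > self.t_dec, 1.0, 0.0)
        return self.amp * self.r**2 * s * (1 - s) * (1 - 2 * s) - self.decline * step


@dataclass(frozen=True)
class SaturatingExp:
    """Monotone saturating curve f(t) = base + amp*(1 - exp(-t/tau)).

    Velocity is maximal at t=0 and strictly decreasing — no spurt, ever.
    """

    base: float
    amp: float
    tau: float

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return self.base + self.amp * (1.0 - np.exp(-t / self.tau))

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        return self.amp / self.tau * np.exp(-t / self.tau)

    def second(self, t):
        t = np.asarray(t, dtype=float)
        return -self.amp / self.tau**2 * np.exp(-t / self.tau)


@dataclass(frozen=True)
class GaussianBump:
    """Transient log-scale elevation f(t) = base + amp*exp(-(t-mu)^2/(2w^2))."""

    base: float
    amp: float
    mu: float
    width: float

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return self.base + self.amp * np.exp(-((t - self.mu) ** 2) / (2 * self.width**2))

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        g = np.exp(-((t - self.mu) ** 2) / (2 * self.width**2))
        return -self.amp * (t - self.mu) / self.width**2 * g

    def second(self, t):
        t = np.asarray(t, dtype=float)
        g = np.exp(-((t - self.mu) ** 2) / (2 * self.width**2))
        return self.amp * g * (((t - self.mu) / self.width**2) ** 2 - 1.0 / self.width**2)
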