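"""Illness-death model transport equation: forward solver and inversion.

The three-state illness-death model (healthy → diseased → dead, healthy →
dead, no remission) links age-specific prevalence p, incidence i and the
state-specific mortalities m0 (non-diseased) and m1 (diseased) through the
transport equation

    (∂/∂t + ∂/∂a) p = (1 - p) [ i - p (m1 - m0) ].

Only the all-cause mortality m = p·m1 + (1-p)·m0 and the mortality-rate
ratio MRR = m1/m0 are observable, so the solver re-derives (m0, m1) from
(p, m, MRR) at every step.  Under the no-calendar-trend assumption the
PDE reduces along characteristics to an ODE in age, which is what
:func:`solve_prevalence` integrates from p(0) = 0 with a classical
fixed-step 4th-order Runge-Kutta scheme (fixed step for bit-reproducibility
across platforms; the right-hand side is smooth).

The inversion reads the same equation for i:

    i = dp/(1-p) + m · p(MRR-1) / (1 + p(MRR-1)),

where dp is the derivative of prevalence along the characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .models import IncidenceParams, MRRParams, incidence_rate, mrr as mrr_curve

__all__ = [
    "PrevalenceCurve",
    "SolverError",
    "split_mortality",
    "prevalence_derivative",
    "solve_prevalence",
    "invert_incidence",
    "incidence_from_curve",
]

DEFAULT_STEP = 0.05
MAX_AGE = 110.0


class SolverError(RuntimeError):
    """Prevalence left [0, 1) during integration (invalid rates upstream)."""


@dataclass
class PrevalenceCurve:
    """Prevalence proportion on an increasing age grid at one calendar time."""

    ages: np.ndarray
    p: np.ndarray
    t_ref: float = 2013.5

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.ages.shape != self.p.shape:
            raise ValueError("ages and p must have the same length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.p < 0) or np.any(self.p >= 1):
            raise ValueError("prevalence must lie in [0, 1)")

    def at(self, a) -> np.ndarray:
        """Linear interpolation of p at arbitrary ages within the grid."""
        return np.interp(np.asarray(a, dtype=float), self.ages, self.p)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "p": self.p}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, t_ref: float = 2013.5) -> "PrevalenceCurve":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(), p=df["p"].to_numpy(), t_ref=t_ref)


def split_mortality(p, m, mrr):
    """Decompose all-cause mortality into (m0, m1) given prevalence and MRR.

    Solves m = p·m1 + (1-p)·m0 together with m1 = MRR·m0:
    m0 = m / (1 + p(MRR-1)), m1 = MRR·m0.  Vectorized.
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    r = np.asarray(mrr, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("prevalence must lie in [0, 1)")
    if np.any(m < 0):
        raise ValueError("all-cause mortality must be >= 0")
    if np.any(r <= 0):
        raise ValueError("MRR must be > 0")
    denom = 1.0 + p * (r - 1.0)
    if np.any(denom <= 0):
        raise ValueError("mortality decomposition denominator not positive")
    m0 = m / denom
    m1 = r * m0
    if m0.ndim == 0:
        return float(m0), float(m1)
    return m0, m1


def prevalence_derivative(a, p, i, m0, m1):
    """Right-hand side (1-p)[i - p(m1-m0)] of the transport equation.

    ``a`` is accepted for signature symmetry with ODE conventions; the
    age-dependence enters through the rates i, m0, m1 evaluated at ``a``.
    """
    p = np.asarray(p, dtype=float)
    out = (1.0 - p) * (np.asarray(i, float) - p * (np.asarray(m1, float) - np.asarray(m0, float)))
    return out if out.ndim else float(out)


def solve_prevalence(
    inc: IncidenceParams,
    mrrp: MRRParams,
    hazard: Callable,
    age_grid: np.ndarray = None,
    step: float = DEFAULT_STEP,
    t_ref: float = 2013.5,
) -> PrevalenceCurve:
    """Integrate prevalence from p(0)=0 along the age characteristic.

    ``hazard`` is the all-cause mortality m(a), vectorized over age.  The
    classical RK4 scheme runs on a uniform grid from 0 to 110 (default step
    0.05 year); rate curves are pre-tabulated at half-step resolution so the
    inner loop is pure arithmetic.
    """
    if age_grid is not None:
        ages = np.asarray(age_grid, dtype=float)
        if ages[0] != 0.0:
            raise ValueError("age grid must start at 0 (boundary condition p(0)=0)")
        steps = np.diff(ages)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("age grid must be uniform and increasing")
        step = float(steps[0])
    else:
        n = int(round(MAX_AGE / step))
        ages = np.linspace(0.0, MAX_AGE, n + 1)
    if step > 0.1 + 1e-12:
        raise ValueError("grid step must be <= 0.1 year")

    n = len(ages) - 1
    half = np.linspace(ages[0], ages[-1], 2 * n + 1)  # nodes and midpoints
    i_arr = np.asarray(incidence_rate(half, inc), dtype=float)
    r_arr = np.asarray(mrr_curve(half, mrrp), dtype=float)
    m_arr = np.asarray(hazard(half), dtype=float)
    if m_arr.shape != half.shape:
        m_arr = np.broadcast_to(m_arr, half.shape).copy()
    if np.any(m_arr < 0) or np.any(r_arr <= 0):
        raise ValueError("hazard must be >= 0 and MRR > 0 on the grid")
    excess = m_arr * (r_arr - 1.0)  # p-independent part of p(m1-m0)·(1+p(r-1))

    out = _rk4_forward(i_arr, excess, r_arr - 1.0, step)
    return PrevalenceCurve(ages=ages, p=out, t_ref=t_ref)


def _rk4_forward(i_arr: np.ndarray, excess: np.ndarray, rm1: np.ndarray, h: float) -> np.ndarray:
    """Classical RK4 for dp/da = (1-p)(i - p·excess/(1+p·rm1)), p(0)=0.

    The rate curves are pre-tabulated on the half-step grid (2n+1 values for
    n steps); ``excess`` is m·(MRR-1) and ``rm1`` is MRR-1, so the bracket is
    the exact i - p(m1-m0) with (m0, m1) re-derived from p at every stage.
    """
    n = (len(i_arr) - 1) // 2
    il = i_arr.tolist()
    el = excess.tolist()
    rl = rm1.tolist()
    p = 0.0
    out = np.empty(n + 1)
    out[0] = 0.0
    h6 = h / 6.0
    h2 = 0.5 * h
    for k in range(n):
        j = 2 * k
        i0, e0, r0 = il[j], el[j], rl[j]
        i1, e1, r1 = il[j + 1], el[j + 1], rl[j + 1]
        i2, e2, r2 = il[j + 2], el[j + 2], rl[j + 2]
        k1 = (1.0 - p) * (i0 - p * e0 / (1.0 + p * r0))
        q = p + h2 * k1
        k2 = (1.0 - q) * (i1 - q * e1 / (1.0 + q * r1))
        q = p + h2 * k2
        k3 = (1.0 - q) * (i1 - q * e1 / (1.0 + q * r1))
        q = p + h * k3
        k4 = (1.0 - q) * (i2 - q * e2 / (1.0 + q * r2))
        p = p + h6 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if p < 0.0:
            if p < -1e-10:
                raise SolverError(f"prevalence left [0,1) at step {k + 1}: p={p:.3e}")
            p = 0.0
        elif p >= 1.0:
            raise SolverError(f"prevalence left [0,1) at step {k + 1}: p={p:.3e}")
        out[k + 1] = p
    return out


def invert_incidence(p, dp, m, mrr):
    """Incidence from prevalence via the inverted transport equation.

    i = dp/(1-p) + m · p(MRR-1)/(1 + p(MRR-1)).  ``dp`` is the prevalence
    derivative along the characteristic (dp/da under no calendar trend).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p >= 1):
        raise ValueError("prevalence must be < 1 (singularity at p=1)")
    if np.any(p < 0):
        raise ValueError("prevalence must be >= 0")
    r = np.asarray(mrr, dtype=float)
    if np.any(r <= 0):
        raise ValueError("MRR must be > 0")
    m = np.asarray(m, dtype=float)
    dp = np.asarray(dp, dtype=float)
    out = dp / (1.0 - p) + m * p * (r - 1.0) / (1.0 + p * (r - 1.0))
    return out if out.ndim else float(out)


def incidence_from_curve(curve: PrevalenceCurve, hazard: Callable, mrrp: MRRParams):
    """Recover i(a) from a solved/observed prevalence curve.

    Differentiates the curve numerically (4th-order central differences on a
    uniform grid, 2nd-order otherwise) and applies :func:`invert_incidence` —
    the observed-data pathway, where no analytic right-hand side exists.
    """
    steps = np.diff(curve.ages)
    if len(steps) >= 4 and np.allclose(steps, steps[0]):
        h = steps[0]
        p = curve.p
        dp = np.gradient(p, curve.ages)  # 2nd-order at the edges
        dp[2:-2] = (-p[4:] + 8.0 * p[3:-1] - 8.0 * p[1:-3] + p[:-4]) / (12.0 * h)
    else:
        dp = np.gradient(curve.p, curve.ages)
    m = np.asarray(hazard(curve.ages), dtype=float)
    r = mrr_curve(curve.ages, mrrp)
    return invert_incidence(curve.p, dp, m, r)
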