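"""Parametric transition-rate models of the illness-death model.

Two parametric curves drive the whole pipeline:

* a Gaussian age-specific incidence rate

  .. math:: i(a) = \\beta_1 \\exp\\!\\left(-\\tfrac12 \\left(\\frac{a-\\beta_2}{\\beta_3}\\right)^2\\right)

  where ``beta1`` is the peak rate (per person-year), ``beta2`` the age of the
  maximum and ``beta3`` the width of the curve (both in years);

* a log-linear mortality-rate ratio (MRR = m1/m0, mortality of diseased over
  non-diseased)

  .. math:: \\log \\mathrm{MRR}(a) = \\gamma_1 + \\frac{a-30}{70}(\\gamma_2-\\gamma_1)

  anchored so that ``gamma1`` and ``gamma2`` are the log MRR at ages 30 and
  100.  The log-linear form is what two Gompertz hazards with different
  baselines imply for the log of their ratio.

Ages are continuous real numbers in years; no rounding happens inside these
functions.  The MRR line extrapolates linearly below age 30 and above age 100
(the forward prevalence solver integrates from age 0, where the diseased
population is negligible, so the extrapolated values carry almost no weight).
Parameters are kept at full floating precision; rounding is a display concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "IncidenceParams",
    "MRRParams",
    "incidence_rate",
    "log_mrr",
    "mrr",
]


@dataclass(frozen=True)
class IncidenceParams:
    """Parameters of the Gaussian age-specific incidence curve.

    Attributes
    ----------
    beta1 : float
        Peak incidence rate, per person-year (``i(beta2) == beta1``).
    beta2 : float
        Age of the maximum, in years.  Must lie in [0, 110].
    beta3 : float
        Width of the curve, in years.  Strictly positive.
    """

    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.beta1, self.beta2, self.beta3)):
            raise ValueError("incidence parameters must be finite")
        if self.beta1 < 0:
            raise ValueError(f"beta1 must be >= 0, got {self.beta1}")
        if self.beta3 <= 0:
            raise ValueError(f"beta3 must be > 0, got {self.beta3}")
        if not 0.0 <= self.beta2 <= 110.0:
            raise ValueError(f"beta2 must be within [0, 110], got {self.beta2}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IncidenceParams":
        return cls(beta1=float(d["beta1"]), beta2=float(d["beta2"]), beta3=float(d["beta3"]))


@dataclass(frozen=True)
class MRRParams:
    """Anchors of the log-linear mortality-rate-ratio model.

    ``gamma1`` is log MRR at age 30, ``gamma2`` log MRR at age 100; both are
    dimensionless and unconstrained in sign (an MRR below one at high ages is
    a perfectly ordinary fit outcome).
    """

    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gamma1) and math.isfinite(self.gamma2)):
            raise ValueError("MRR parameters must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MRRParams":
        return cls(gamma1=float(d["gamma1"]), gamma2=float(d["gamma2"]))


def _check_finite_age(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("age must be finite")
    return arr


def incidence_rate(a, params: IncidenceParams):
    """Gaussian incidence rate ``i(a)``, per person-year.

    Vectorized over ``a``.  The maximum value ``beta1`` is attained exactly at
    ``a == beta2`` and the curve is symmetric about that age.
    """
    if not isinstance(params, IncidenceParams):
        params = IncidenceParams(*params)
    arr = _check_finite_age(a)
    z = (arr - params.beta2) / params.beta3
    out = params.beta1 * np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def log_mrr(a, params: MRRParams):
    """Log mortality-rate ratio at age ``a`` (linear in age, anchored at 30/100)."""
    if not isinstance(params, MRRParams):
        params = MRRParams(*params)
    arr = _check_finite_age(a)
    out = params.gamma1 + (arr - 30.0) / 70.0 * (params.gamma2 - params.gamma1)
    return out if out.ndim else float(out)


def mrr(a, params: MRRParams):
    """Mortality-rate ratio ``exp(log_mrr(a))``; strictly positive."""
    out = np.exp(log_mrr(a, params))
    return out if np.ndim(out) else float(out)
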