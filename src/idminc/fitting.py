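"""Least-squares estimation of incidence and MRR parameters.

Observed data are Zi-style aggregated prevalence proportions: one proportion
per (sex, year, age group) with a person-count denominator, on the groups
0-24, 25-34, ..., 75-84, 85-109.  The fit estimates (beta1, beta3, gamma1,
gamma2) with the peak age beta2 held fixed (87.5 by default; the peak
location is not identifiable from eight aggregated proportions and is pinned
to external evidence).

Two objective modes are provided, reflecting a genuine ambiguity in how a
trajectory can be matched to grouped cross-sectional data:

* ``"trajectory"`` (default): forward-solve the illness-death ODE at the
  candidate parameters, aggregate the solved prevalence to the observed
  groups, and take the sum of squared prevalence residuals.  Differentiating
  eight noisy proportions is ill-conditioned; matching trajectories uses the
  same model and data and coincides with the derivative route in the
  noiseless limit.
* ``"derivative"``: difference the observed group prevalences across the
  groups' representative ages (2nd-order central differences), plug the
  result into the inverted transport equation to get point-wise incidence
  estimates, and match those against the parametric Gaussian.

Group aggregation likewise has two documented options: evaluate the solved
curve at each group's representative age (midpoint; the open 85-109 group is
represented by age 91 ≈ 85 + remaining life expectancy) or average it over
the group with stationary-population weights exp(-∫m).

Years are pooled by averaging the observed proportions per group, giving a
single cross-section at the study midpoint.

The sklearn-style front end is :class:`IDMIncidenceEstimator`; the
module-level functions are the underlying plumbing and remain usable on
their own.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .models import IncidenceParams, MRRParams, incidence_rate, mrr as mrr_curve
from .pde import invert_incidence, solve_prevalence

__all__ = [
    "FitResult",
    "IDMIncidenceEstimator",
    "representative_ages",
    "model_group_prevalence",
    "objective",
    "fit",
    "pool_years",
    "validate_groups",
]

log = logging.getLogger(__name__)

PREV_COLUMNS = ["sex", "year", "age_lo", "age_hi", "prev", "denom"]

DEFAULT_TOP_AGE = 91.0
DEFAULT_START = (0.05, 25.0, 0.4, 0.0)

# box constraints on (beta1, beta3, gamma1, gamma2); violations are mapped to
# a large finite penalty so derivative-free optimizers stay well-defined
BOUNDS = {
    "beta1": (0.0, 1.0),
    "beta3": (1.0, 80.0),
    "gamma1": (-3.0, 3.0),
    "gamma2": (-3.0, 3.0),
}
PENALTY = 1e6


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    ``params`` and ``mrr_params`` are on the natural scale; ``start`` records
    the (beta1, beta3, gamma1, gamma2) starting point actually used by the
    winning restart.
    """

    params: IncidenceParams
    mrr_params: MRRParams
    objective: float
    converged: bool
    n_evals: int
    start: tuple
    boundary: bool = False
    message: str = ""

    @property
    def theta(self) -> tuple:
        return (
            self.params.beta1,
            self.params.beta3,
            self.mrr_params.gamma1,
            self.mrr_params.gamma2,
        )

    def to_dict(self) -> dict:
        return {
            "beta1": self.params.beta1,
            "beta2": self.params.beta2,
            "beta3": self.params.beta3,
            "gamma1": self.mrr_params.gamma1,
            "gamma2": self.mrr_params.gamma2,
            "objective": self.objective,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_evals": self.n_evals,
            "start": list(self.start),
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def validate_groups(observed: pd.DataFrame) -> pd.DataFrame:
    """Check the aggregated-prevalence schema and group structure."""
    missing = set(PREV_COLUMNS) - set(observed.columns)
    if missing:
        raise ValueError(f"observed prevalence missing columns: {sorted(missing)}")
    if (observed["denom"] <= 0).any():
        raise ValueError("denominators must be positive")
    if ((observed["prev"] < 0) | (observed["prev"] > 1)).any():
        raise ValueError("prevalence proportions must lie in [0, 1]")
    groups = (
        observed[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo").to_numpy()
    )
    for (lo1, hi1), (lo2, _hi2) in zip(groups[:-1], groups[1:]):
        if lo2 <= hi1:
            raise ValueError(f"age groups overlap: [{lo1},{hi1}] and [{lo2},{_hi2}]")
    return observed


def representative_ages(groups: pd.DataFrame, top_age: float = DEFAULT_TOP_AGE) -> np.ndarray:
    """One representative age per group, in ascending group order.

    Closed groups map to their interval midpoint on integer-year bounds,
    (lo + hi + 1)/2 — e.g. 25-34 → 30.  The open-ended top group (the one
    with the highest lower bound) maps to ``top_age``: survivors past 85
    have about six years of remaining life expectancy, so their average age
    is near 91.
    """
    g = groups[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
    lo = g["age_lo"].to_numpy(dtype=float)
    hi = g["age_hi"].to_numpy(dtype=float)
    for i in range(len(lo) - 1):
        if lo[i + 1] <= hi[i]:
            raise ValueError("age groups overlap")
    ages = (lo + hi + 1.0) / 2.0
    if len(ages):
        ages[-1] = top_age
    return ages


def pool_years(observed: pd.DataFrame) -> pd.DataFrame:
    """Average observed prevalence per group across calendar years.

    Denominators are summed: the pooled proportion's sampling scale is that
    of the combined person-count.  Assumes one row per (year, group).
    """
    pooled = (
        observed.groupby(["age_lo", "age_hi"], as_index=False)
        .agg(prev=("prev", "mean"), denom=("denom", "sum"))
        .sort_values("age_lo")
        .reset_index(drop=True)
    )
    return pooled


def _stationary_weights(ages: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Survival curve exp(-∫m) on a uniform age grid (trapezoid cumulation)."""
    from scipy.integrate import cumulative_trapezoid

    H = cumulative_trapezoid(m, ages, initial=0.0)
    return np.exp(-H)


def model_group_prevalence(
    inc: IncidenceParams,
    mrrp: MRRParams,
    hazard: Callable,
    groups: pd.DataFrame,
    top_age: float = DEFAULT_TOP_AGE,
    aggregate: str = "midpoint",
    step: float = 0.05,
) -> np.ndarray:
    """Model-predicted prevalence for each observed age group.

    ``aggregate='midpoint'`` evaluates the solved curve at each group's
    representative age; ``'weighted'`` averages it over the group's ages with
    stationary-population weights exp(-∫m) (the denominator-profile a
    constant-mortality population would have).
    """
    curve = solve_prevalence(inc, mrrp, hazard, step=step)
    g = groups[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
    if aggregate == "midpoint":
        ages = representative_ages(g, top_age=top_age)
        return curve.at(ages)
    if aggregate == "weighted":
        m = np.asarray(hazard(curve.ages), dtype=float)
        w = _stationary_weights(curve.ages, m)
        out = []
        for lo, hi in g.to_numpy(dtype=float):
            mask = (curve.ages >= lo) & (curve.ages < hi + 1.0)
            out.append(np.average(curve.p[mask], weights=w[mask]))
        return np.asarray(out)
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def _derivative_objective(
    theta: np.ndarray,
    fixed_beta2: float,
    pooled: pd.DataFrame,
    hazard: Callable,
    top_age: float,
    weights: np.ndarray,
) -> float:
    beta1, beta3, gamma1, gamma2 = theta
    inc = IncidenceParams(beta1, fixed_beta2, beta3)
    mp = MRRParams(gamma1, gamma2)
    ages = representative_ages(pooled, top_age=top_age)
    p_obs = pooled["prev"].to_numpy(dtype=float)
    dp = np.gradient(p_obs, ages)
    m = np.asarray(hazard(ages), dtype=float)
    r = mrr_curve(ages, mp)
    i_obs = invert_incidence(np.clip(p_obs, 0.0, 1.0 - 1e-12), dp, m, r)
    resid = i_obs - incidence_rate(ages, inc)
    return float(np.sum(weights * resid * resid))


def objective(
    theta: Sequence[float],
    fixed_beta2: float,
    observed: pd.DataFrame,
    hazard: Callable,
    mode: str = "trajectory",
    aggregate: str = "midpoint",
    weight_by_denom: bool = False,
    top_age: float = DEFAULT_TOP_AGE,
    step: float = 0.05,
) -> float:
    """Sum-of-squares objective over groups (years pooled).

    Out-of-bounds ``theta`` returns a large finite penalty growing with the
    violation, never an exception, so simplex moves stay safe.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4,):
        raise ValueError("theta must be (beta1, beta3, gamma1, gamma2)")
    # beta1 == 0 (the zero-height curve) is a legitimate degenerate model and
    # draws no penalty; everything outside the box maps to a large finite
    # value that grows with the violation so simplex moves stay well-defined.
    pen = _bounds_penalty(theta)
    if pen is not None:
        return pen

    pooled = pool_years(validate_groups(observed) if "sex" in observed.columns else observed)
    w = pooled["denom"].to_numpy(dtype=float) if weight_by_denom else np.ones(len(pooled))
    if weight_by_denom:
        w = w / w.sum()

    if mode == "derivative":
        return _derivative_objective(theta, fixed_beta2, pooled, hazard, top_age, w)
    if mode != "trajectory":
        raise ValueError(f"unknown objective mode {mode!r}")

    beta1, beta3, gamma1, gamma2 = theta
    try:
        pred = model_group_prevalence(
            IncidenceParams(beta1, fixed_beta2, beta3),
            MRRParams(gamma1, gamma2),
            hazard,
            pooled,
            top_age=top_age,
            aggregate=aggregate,
            step=step,
        )
    except (ValueError, RuntimeError):
        return PENALTY
    resid = pooled["prev"].to_numpy(dtype=float) - pred
    return float(np.sum(w * resid * resid))


def _bounds_penalty(theta: np.ndarray) -> Optional[float]:
    if not np.all(np.isfinite(theta)):
        return PENALTY * 10
    dist = 0.0
    for v, key in zip(theta, ("beta1", "beta3", "gamma1", "gamma2")):
        lo, hi = BOUNDS[key]
        if v < lo:
            dist += lo - v
        elif v > hi:
            dist += v - hi
    if dist > 0:
        return PENALTY * (1.0 + dist)
    return None


def _objective_factory(
    observed: pd.DataFrame,
    hazard: Callable,
    fixed_beta2: float,
    mode: str,
    aggregate: str,
    weight_by_denom: bool,
    top_age: float,
    step: float,
) -> Callable:
    """Precompute everything theta-independent; return a numpy-only objective.

    Same mathematics as :func:`objective` (asserted by a unit test), minus
    the per-call DataFrame work — the optimizer calls this thousands of
    times per fit.
    """
    from .pde import MAX_AGE, _rk4_forward

    pooled = pool_years(observed)
    prev_obs = pooled["prev"].to_numpy(dtype=float)
    if weight_by_denom:
        w = pooled["denom"].to_numpy(dtype=float)
        w = w / w.sum()
    else:
        w = np.ones(len(pooled))
    rep_ages = representative_ages(pooled, top_age=top_age)

    if mode == "derivative":
        dp = np.gradient(prev_obs, rep_ages)
        m_rep = np.asarray(hazard(rep_ages), dtype=float)
        p_clip = np.clip(prev_obs, 0.0, 1.0 - 1e-12)
        s = (rep_ages - 30.0) / 70.0

        def f_deriv(theta):
            pen = _bounds_penalty(theta)
            if pen is not None:
                return pen
            beta1, beta3, gamma1, gamma2 = theta
            r = np.exp(gamma1 + s * (gamma2 - gamma1))
            i_obs = dp / (1.0 - p_clip) + m_rep * p_clip * (r - 1.0) / (1.0 + p_clip * (r - 1.0))
            z = (rep_ages - fixed_beta2) / beta3
            resid = i_obs - beta1 * np.exp(-0.5 * z * z)
            return float(np.sum(w * resid * resid))

        return f_deriv

    if mode != "trajectory":
        raise ValueError(f"unknown objective mode {mode!r}")

    n = int(round(MAX_AGE / step))
    node_ages = np.linspace(0.0, MAX_AGE, n + 1)
    half = np.linspace(0.0, MAX_AGE, 2 * n + 1)
    m_arr = np.asarray(hazard(half), dtype=float)
    if m_arr.shape != half.shape:
        m_arr = np.broadcast_to(m_arr, half.shape).copy()
    s_half = (half - 30.0) / 70.0

    if aggregate == "weighted":
        from .fitting import _stationary_weights

        surv = _stationary_weights(node_ages, m_arr[::2])
        group_masks = [
            (node_ages >= lo) & (node_ages < hi + 1.0)
            for lo, hi in pooled[["age_lo", "age_hi"]].to_numpy(dtype=float)
        ]
    elif aggregate != "midpoint":
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    def f_traj(theta):
        pen = _bounds_penalty(theta)
        if pen is not None:
            return pen
        beta1, beta3, gamma1, gamma2 = theta
        z = (half - fixed_beta2) / beta3
        i_arr = beta1 * np.exp(-0.5 * z * z)
        rm1 = np.exp(gamma1 + s_half * (gamma2 - gamma1)) - 1.0
        try:
            p = _rk4_forward(i_arr, m_arr * rm1, rm1, step)
        except RuntimeError:
            return PENALTY
        if aggregate == "midpoint":
            pred = np.interp(rep_ages, node_ages, p)
        else:
            pred = np.array([np.average(p[mk], weights=surv[mk]) for mk in group_masks])
        resid = prev_obs - pred
        return float(np.sum(w * resid * resid))

    return f_traj


def _to_internal(theta: np.ndarray) -> np.ndarray:
    """(beta1, beta3, g1, g2) -> (log beta1, log beta3, g1, g2)."""
    return np.array([np.log(max(theta[0], 1e-12)), np.log(theta[1]), theta[2], theta[3]])


def _from_internal(x: np.ndarray) -> np.ndarray:
    return np.array([np.exp(x[0]), np.exp(x[1]), x[2], x[3]])


def fit(
    observed: pd.DataFrame,
    hazard: Callable,
    fixed_beta2: float = 87.5,
    start: Sequence[float] = DEFAULT_START,
    seed: Optional[int] = None,
    n_restarts: int = 3,
    mode: str = "trajectory",
    aggregate: str = "midpoint",
    weight_by_denom: bool = False,
    top_age: float = DEFAULT_TOP_AGE,
    step: float = 0.05,
    maxiter: int = 2000,
) -> FitResult:
    """Estimate (beta1, beta3, gamma1, gamma2) by derivative-free least squares.

    Runs a Nelder-Mead simplex from ``start`` plus ``n_restarts`` seeded
    random perturbations of it (log-scale jitter on the betas); the lowest
    objective wins, ties broken by run order.  beta1 and beta3 are optimized
    on the log scale to enforce positivity.  Non-convergence is reported in
    the result, never raised.
    """
    validate_groups(observed)
    pooled_groups = observed[["age_lo", "age_hi"]].drop_duplicates()
    if len(pooled_groups) < 4:
        raise ValueError(
            f"need >= 4 informative age groups to identify 4 parameters, got {len(pooled_groups)}"
        )

    rng = np.random.default_rng(seed)
    start = np.asarray(start, dtype=float)
    starts = [start]
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, [0.3, 0.15, 0.1, 0.05])
        s = _from_internal(_to_internal(start) + jitter)
        starts.append(s)

    obj = _objective_factory(
        validate_groups(observed),
        hazard,
        fixed_beta2,
        mode,
        aggregate,
        weight_by_denom,
        top_age,
        step,
    )

    def f(x):
        return obj(_from_internal(x))

    best = None
    best_start = None
    total_evals = 0
    for s in starts:
        res = minimize(
            f,
            _to_internal(s),
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": 1e-6,
                "fatol": 1e-14,
                "adaptive": False,
            },
        )
        total_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
            best_start = s
    theta = _from_internal(best.x)
    beta1, beta3, gamma1, gamma2 = theta
    boundary = bool(
        beta1 < 1e-5
        or beta3 <= BOUNDS["beta3"][0] * 1.001
        or beta3 >= BOUNDS["beta3"][1] * 0.999
        or abs(gamma1) >= 2.99
        or abs(gamma2) >= 2.99
    )
    converged = bool(best.success) and np.isfinite(best.fun) and not boundary
    if not converged:
        log.warning("fit did not converge cleanly: %s (boundary=%s)", best.message, boundary)
    return FitResult(
        params=IncidenceParams(beta1, fixed_beta2, beta3),
        mrr_params=MRRParams(gamma1, gamma2),
        objective=float(best.fun),
        converged=converged,
        n_evals=total_evals,
        start=tuple(np.asarray(best_start, dtype=float)),
        boundary=boundary,
        message=str(best.message),
    )


class IDMIncidenceEstimator(RegressorMixin, BaseEstimator):
    """Illness-death-model incidence estimator with an sklearn interface.

    ``fit(X)`` takes a DataFrame of aggregated prevalence observations
    (columns sex, year, age_lo, age_hi, prev, denom; one sex at a time) and
    estimates the Gaussian incidence curve and log-linear MRR by nonlinear
    least squares with the peak age held at ``fixed_beta2``.  ``predict(a)``
    returns the fitted incidence rate per person-year at ages ``a``.

    Parameters
    ----------
    hazard : callable
        All-cause mortality m(a), vectorized over age (e.g.
        ``MortalityTable.hazard(sex, t)`` or a Gompertz closure).
    fixed_beta2 : float, default 87.5
        Age of the incidence maximum, held fixed during optimization.
    objective_mode : {'trajectory', 'derivative'}
    aggregate : {'midpoint', 'weighted'}
    weight_by_denom : bool
        Weight group residuals by their person-count denominators.
    top_age : float, default 91.0
        Representative age of the open-ended top group.
    start : tuple
        Starting values (beta1, beta3, gamma1, gamma2).
    n_restarts : int
        Seeded random restarts of the simplex in addition to ``start``.
    step : float
        Age step of the forward ODE solver, years.
    random_state : int or None
        Seed for the restart jitter.

    Attributes
    ----------
    incidence_params_ : IncidenceParams
    mrr_params_ : MRRParams
    beta1_, beta3_, gamma1_, gamma2_ : float
    objective_ : float
        Sum of squared residuals at the optimum.
    converged_ : bool
    result_ : FitResult
    """

    def __init__(
        self,
        hazard: Callable = None,
        fixed_beta2: float = 87.5,
        objective_mode: str = "trajectory",
        aggregate: str = "midpoint",
        weight_by_denom: bool = False,
        top_age: float = DEFAULT_TOP_AGE,
        start: tuple = DEFAULT_START,
        n_restarts: int = 3,
        step: float = 0.05,
        random_state: Optional[int] = None,
    ):
        self.hazard = hazard
        self.fixed_beta2 = fixed_beta2
        self.objective_mode = objective_mode
        self.aggregate = aggregate
        self.weight_by_denom = weight_by_denom
        self.top_age = top_age
        self.start = start
        self.n_restarts = n_restarts
        self.step = step
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "IDMIncidenceEstimator":
        if self.hazard is None:
            raise ValueError("hazard must be provided")
        X = validate_groups(pd.DataFrame(X))
        sexes = X["sex"].unique()
        if len(sexes) > 1:
            raise ValueError(
                f"fit one sex at a time (got {sorted(sexes)}); the pipelines are independent"
            )
        result = fit(
            X,
            self.hazard,
            fixed_beta2=self.fixed_beta2,
            start=self.start,
            seed=self.random_state,
            n_restarts=self.n_restarts,
            mode=self.objective_mode,
            aggregate=self.aggregate,
            weight_by_denom=self.weight_by_denom,
            top_age=self.top_age,
            step=self.step,
        )
        self.result_ = result
        self.incidence_params_ = result.params
        self.mrr_params_ = result.mrr_params
        self.beta1_ = result.params.beta1
        self.beta3_ = result.params.beta3
        self.gamma1_ = result.mrr_params.gamma1
        self.gamma2_ = result.mrr_params.gamma2
        self.objective_ = result.objective
        self.converged_ = result.converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, ages) -> np.ndarray:
        """Fitted incidence rate per person-year at ``ages``."""
        self._check_fitted()
        return np.asarray(incidence_rate(np.asarray(ages, dtype=float), self.incidence_params_))

    def predict_prevalence(self, ages) -> np.ndarray:
        """Model prevalence at ``ages`` from the fitted parameters."""
        self._check_fitted()
        curve = solve_prevalence(self.incidence_params_, self.mrr_params_, self.hazard, step=self.step)
        return curve.at(ages)

    def predict_mrr(self, ages) -> np.ndarray:
        self._check_fitted()
        return np.asarray(mrr_curve(np.asarray(ages, dtype=float), self.mrr_params_))

    def _check_fitted(self) -> None:
        if not hasattr(self, "incidence_params_"):
            raise AttributeError("estimator is not fitted; call fit(X) first")
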