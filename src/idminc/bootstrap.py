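"""Perturbation bootstrap for aggregated prevalence data.

With only aggregated proportions available there are no individuals to
resample, so uncertainty is propagated by re-noising the observed
proportions: each (sex, year, age-group) cell gets an independent Gaussian
perturbation whose standard deviation is the binomial standard error
sqrt(p(1-p)/n) of that cell, the model is refitted, and the fitted
age-specific incidence is recorded.  Medians and the 2.5%/97.5% empirical
quantiles over the replicates give the point estimates and 95% confidence
intervals.

Each replicate draws from its own RNG stream seeded by (seed, replicate
index), so results are independent of execution order and replicates could
be run in parallel without changing the summary.

Reported incidence follows the interval-midpoint convention: the table row
labelled L is the fitted curve evaluated at L + 2.5 (the midpoint of the
5-year interval [L, L+5)), scaled to cases per 10,000 person-years.  With a
peak age of 87.5 this makes the row labelled 85 equal the peak height and
rows symmetric about it; a flag evaluates at the raw label instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import (
    DEFAULT_START,
    DEFAULT_TOP_AGE,
    FitResult,
    fit,
    validate_groups,
)
from .models import IncidenceParams, MRRParams, incidence_rate

__all__ = [
    "BootstrapSummary",
    "BootstrapError",
    "PerturbationBootstrap",
    "perturb_prevalence",
    "evaluate_incidence_table",
    "run_bootstrap",
    "DEFAULT_EVAL_LABELS",
]

log = logging.getLogger(__name__)

DEFAULT_EVAL_LABELS = tuple(range(30, 100, 5))  # 30, 35, ..., 95
PER = 1e4  # rates reported per 10,000 person-years
PARAM_NAMES = ("beta1", "beta3", "gamma1", "gamma2")


class BootstrapError(RuntimeError):
    """Too many replicates failed to converge — data/model mismatch signal."""


@dataclass
class BootstrapSummary:
    """Medians and 95% quantile intervals over bootstrap replicates."""

    eval_ages: np.ndarray          # row labels (years)
    incidence_median: np.ndarray   # per 10,000 person-years
    incidence_lo: np.ndarray       # 2.5% quantile
    incidence_hi: np.ndarray       # 97.5% quantile
    param_median: dict
    param_lo: dict
    param_hi: dict
    B: int
    seed: Optional[int]
    n_dropped: int = 0
    sex: str = ""

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if np.any(self.incidence_lo > self.incidence_median) or np.any(
            self.incidence_median > self.incidence_hi
        ):
            raise ValueError("quantile sandwich violated: need lo <= median <= hi")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.eval_ages,
                "median": self.incidence_median,
                "lo": self.incidence_lo,
                "hi": self.incidence_hi,
                "sex": self.sex,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "B": self.B,
            "seed": self.seed,
            "n_dropped": self.n_dropped,
            "eval_ages": np.asarray(self.eval_ages).tolist(),
            "incidence_median": np.asarray(self.incidence_median).tolist(),
            "incidence_lo": np.asarray(self.incidence_lo).tolist(),
            "incidence_hi": np.asarray(self.incidence_hi).tolist(),
            "param_median": self.param_median,
            "param_lo": self.param_lo,
            "param_hi": self.param_hi,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BootstrapSummary":
        return cls(
            eval_ages=np.asarray(d["eval_ages"], dtype=float),
            incidence_median=np.asarray(d["incidence_median"], dtype=float),
            incidence_lo=np.asarray(d["incidence_lo"], dtype=float),
            incidence_hi=np.asarray(d["incidence_hi"], dtype=float),
            param_median=d["param_median"],
            param_lo=d["param_lo"],
            param_hi=d["param_hi"],
            B=int(d["B"]),
            seed=d.get("seed"),
            n_dropped=int(d.get("n_dropped", 0)),
            sex=d.get("sex", ""),
        )


def perturb_prevalence(
    observed: pd.DataFrame, rng: np.random.Generator, noise_scale: float = 1.0
) -> pd.DataFrame:
    """Re-noise each cell's proportion with its binomial standard error.

    prev -> prev + eps, eps ~ Normal(0, noise_scale * sqrt(prev(1-prev)/denom)),
    truncated to [0, 1]; cells are independent.  ``noise_scale=0`` returns an
    identical copy (the infinite-denominator limit).
    """
    validate_groups(observed)
    out = observed.copy()
    p = out["prev"].to_numpy(dtype=float)
    n = out["denom"].to_numpy(dtype=float)
    sd = noise_scale * np.sqrt(p * (1.0 - p) / n)
    eps = rng.normal(0.0, 1.0, size=len(p)) * sd
    out["prev"] = np.clip(p + eps, 0.0, 1.0)
    return out


def evaluate_incidence_table(
    params: IncidenceParams,
    eval_labels: Sequence[float] = DEFAULT_EVAL_LABELS,
    at_midpoint: bool = True,
) -> np.ndarray:
    """Incidence per 10,000 person-years at each table row label.

    Row label L is evaluated at L + 2.5 (interval midpoint) by default, or at
    L itself with ``at_midpoint=False``.
    """
    labels = np.asarray(eval_labels, dtype=float)
    ages = labels + 2.5 if at_midpoint else labels
    return np.asarray(incidence_rate(ages, params), dtype=float) * PER


def _replicate_rng(seed: Optional[int], b: int) -> np.random.Generator:
    # stream keyed by (seed, replicate index): order-independent by contract
    return np.random.default_rng(np.random.SeedSequence((0 if seed is None else seed, b)))


def run_bootstrap(
    observed: pd.DataFrame,
    hazard: Callable,
    B: int = 1000,
    fixed_beta2: float = 87.5,
    seed: Optional[int] = 0,
    eval_labels: Sequence[float] = DEFAULT_EVAL_LABELS,
    at_midpoint: bool = True,
    noise_scale: float = 1.0,
    start: Sequence[float] = DEFAULT_START,
    n_restarts: int = 3,
    mode: str = "trajectory",
    aggregate: str = "midpoint",
    weight_by_denom: bool = False,
    top_age: float = DEFAULT_TOP_AGE,
    step: float = 0.05,
    max_dropped_frac: float = 0.2,
) -> BootstrapSummary:
    """Perturb → refit → summarize, B times.

    A base fit on the unperturbed data (with restarts) supplies the warm
    start for every replicate, which then runs a single simplex; replicates
    that fail to converge are dropped with a logged count, and more than
    ``max_dropped_frac`` of them failing raises :class:`BootstrapError`.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    validate_groups(observed)
    sexes = observed["sex"].unique()
    sex = str(sexes[0]) if len(sexes) == 1 else ""

    base = fit(
        observed,
        hazard,
        fixed_beta2=fixed_beta2,
        start=start,
        seed=seed,
        n_restarts=n_restarts,
        mode=mode,
        aggregate=aggregate,
        weight_by_denom=weight_by_denom,
        top_age=top_age,
        step=step,
    )
    warm = (base.params.beta1, base.params.beta3, base.mrr_params.gamma1, base.mrr_params.gamma2)
    if not base.converged:
        log.warning("base fit not converged; bootstrap proceeds from its best point")

    thetas = []
    n_dropped = 0
    for b in range(B):
        rng = _replicate_rng(seed, b)
        perturbed = perturb_prevalence(observed, rng, noise_scale=noise_scale)
        res = fit(
            perturbed,
            hazard,
            fixed_beta2=fixed_beta2,
            start=warm,
            seed=None,
            n_restarts=0,
            mode=mode,
            aggregate=aggregate,
            weight_by_denom=weight_by_denom,
            top_age=top_age,
            step=step,
        )
        if res.converged:
            thetas.append(res.theta)
        else:
            n_dropped += 1
    if n_dropped:
        log.warning("bootstrap: dropped %d/%d non-converged replicates", n_dropped, B)
    if n_dropped > max_dropped_frac * B:
        raise BootstrapError(
            f"{n_dropped}/{B} replicates failed to converge (> {max_dropped_frac:.0%})"
        )

    thetas = np.asarray(thetas)  # (B_kept, 4)
    inc_tables = np.stack(
        [
            evaluate_incidence_table(
                IncidenceParams(t[0], fixed_beta2, t[1]), eval_labels, at_midpoint=at_midpoint
            )
            for t in thetas
        ]
    )
    q = np.quantile(inc_tables, [0.025, 0.5, 0.975], axis=0)
    pq = np.quantile(thetas, [0.025, 0.5, 0.975], axis=0)
    return BootstrapSummary(
        eval_ages=np.asarray(eval_labels, dtype=float),
        incidence_median=q[1],
        incidence_lo=q[0],
        incidence_hi=q[2],
        param_median=dict(zip(PARAM_NAMES, pq[1].tolist())),
        param_lo=dict(zip(PARAM_NAMES, pq[0].tolist())),
        param_hi=dict(zip(PARAM_NAMES, pq[2].tolist())),
        B=B,
        seed=seed,
        n_dropped=n_dropped,
        sex=sex,
    )


class PerturbationBootstrap(BaseEstimator):
    """sklearn-style wrapper around :func:`run_bootstrap`.

    ``fit(X)`` runs the full perturb-refit-summarize procedure on an
    aggregated-prevalence DataFrame (one sex) and stores the result in
    ``summary_``; ``predict(labels)`` returns the median incidence table
    (per 10,000 person-years) at the requested row labels.
    """

    def __init__(
        self,
        hazard: Callable = None,
        B: int = 1000,
        fixed_beta2: float = 87.5,
        seed: Optional[int] = 0,
        eval_labels: tuple = DEFAULT_EVAL_LABELS,
        at_midpoint: bool = True,
        noise_scale: float = 1.0,
        start: tuple = DEFAULT_START,
        n_restarts: int = 3,
        objective_mode: str = "trajectory",
        aggregate: str = "midpoint",
        weight_by_denom: bool = False,
        top_age: float = DEFAULT_TOP_AGE,
        step: float = 0.05,
    ):
        self.hazard = hazard
        self.B = B
        self.fixed_beta2 = fixed_beta2
        self.seed = seed
        self.eval_labels = eval_labels
        self.at_midpoint = at_midpoint
        self.noise_scale = noise_scale
        self.start = start
        self.n_restarts = n_restarts
        self.objective_mode = objective_mode
        self.aggregate = aggregate
        self.weight_by_denom = weight_by_denom
        self.top_age = top_age
        self.step = step

    def fit(self, X: pd.DataFrame, y=None) -> "PerturbationBootstrap":
        if self.hazard is None:
            raise ValueError("hazard must be provided")
        self.summary_ = run_bootstrap(
            pd.DataFrame(X),
            self.hazard,
            B=self.B,
            fixed_beta2=self.fixed_beta2,
            seed=self.seed,
            eval_labels=self.eval_labels,
            at_midpoint=self.at_midpoint,
            noise_scale=self.noise_scale,
            start=self.start,
            n_restarts=self.n_restarts,
            mode=self.objective_mode,
            aggregate=self.aggregate,
            weight_by_denom=self.weight_by_denom,
            top_age=self.top_age,
            step=self.step,
        )
        pm = self.summary_.param_median
        self.incidence_params_ = IncidenceParams(pm["beta1"], self.fixed_beta2, pm["beta3"])
        self.mrr_params_ = MRRParams(pm["gamma1"], pm["gamma2"])
        return self

    def predict(self, labels=None) -> np.ndarray:
        if not hasattr(self, "summary_"):
            raise AttributeError("not fitted")
        if labels is None:
            return np.asarray(self.summary_.incidence_median)
        return evaluate_incidence_table(self.incidence_params_, labels, at_midpoint=self.at_midpoint)
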