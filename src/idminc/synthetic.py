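"""Synthetic aggregated-prevalence and mortality data with known truth.

Emulates the structure of the German statutory-health-insurance claims
prevalence publication the pipeline was built for: diagnosed-hypertension
prevalence proportions by sex and the eight age groups 0-24, 25-34, ...,
75-84, 85-109, for the calendar years 2009-2018, with person-count
denominators in the millions (about 70 million insured in total), plus an
HMD-style all-cause mortality table.

The generative model is exactly the pipeline's own forward model: prevalence
solves the illness-death ODE at known true parameters, is aggregated to the
groups, and is then observed through binomial sampling at the cell
denominators.  The default true parameters are the hypertension point
estimates the pipeline is meant to recover (male peak 0.0763/person-year at
age 87.5, width 25.337 y, log MRR 0.408 → -0.0171; female 0.0635, 25.18237,
0.321 → -0.0376); the default Gompertz hazards are calibrated to a
German-like schedule (life expectancy at birth ≈ 78/83 years, e(85) ≈ 6
years).  What the generator does NOT emulate: diagnostic coding behaviour,
under-diagnosis, calendar trends in prevalence, private-insurance selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fitting import PREV_COLUMNS, model_group_prevalence, validate_groups
from .lifetable import GompertzParams, MortalityTable
from .models import IncidenceParams, MRRParams

__all__ = [
    "SyntheticConfig",
    "DEFAULT_GROUPS",
    "DEFAULT_DENOMS",
    "generate_truth",
    "add_sampling_noise",
    "generate_dataset",
]

SEXES = ("male", "female")

# Zi age-group schema: closed groups plus the open-ended 85-109 top group
DEFAULT_GROUPS = (
    (0, 24),
    (25, 34),
    (35, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 84),
    (85, 109),
)

# per-sex person counts per group, loosely following the German population
# pyramid at ~35 million insured per sex
DEFAULT_DENOMS = (9_000_000, 5_000_000, 5_000_000, 6_500_000, 5_500_000, 4_500_000, 3_500_000, 1_000_000)

# Gompertz hazards calibrated so that life expectancy at birth and at 85 are
# German-like (see docs/methods.md); overridable through the config
DEFAULT_GOMPERTZ = {
    "male": GompertzParams(g0=-10.707, g1=0.10043),
    "female": GompertzParams(g0=-12.430, g1=0.11696),
}

DEFAULT_TRUE_INC = {
    "male": IncidenceParams(beta1=0.0763, beta2=87.5, beta3=25.33680),
    "female": IncidenceParams(beta1=0.0635, beta2=87.5, beta3=25.18237),
}

DEFAULT_TRUE_MRR = {
    "male": MRRParams(gamma1=0.408, gamma2=-0.0171),
    "female": MRRParams(gamma1=0.321, gamma2=-0.0376),
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    true_inc: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_INC))
    true_mrr: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_MRR))
    gompertz: dict = field(default_factory=lambda: dict(DEFAULT_GOMPERTZ))
    years: tuple = tuple(range(2009, 2019))
    groups: tuple = DEFAULT_GROUPS
    denoms: dict = field(
        default_factory=lambda: {s: tuple(DEFAULT_DENOMS) for s in SEXES}
    )
    noise: str = "binomial"  # or "none"
    seed: Optional[int] = 0
    top_age: float = 91.0
    aggregate: str = "midpoint"
    step: float = 0.05

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("years must be non-empty")
        for s in SEXES:
            if any(d <= 0 for d in self.denoms.get(s, ())):
                raise ValueError("denominators must be positive")
        if self.noise not in ("binomial", "none"):
            raise ValueError("noise must be 'binomial' or 'none'")

    def to_dict(self) -> dict:
        return {
            "true_inc": {s: p.to_dict() for s, p in self.true_inc.items()},
            "true_mrr": {s: p.to_dict() for s, p in self.true_mrr.items()},
            "gompertz": {s: p.to_dict() for s, p in self.gompertz.items()},
            "years": list(self.years),
            "groups": [list(g) for g in self.groups],
            "denoms": {s: list(v) for s, v in self.denoms.items()},
            "noise": self.noise,
            "seed": self.seed,
            "top_age": self.top_age,
            "aggregate": self.aggregate,
            "step": self.step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        kw = {}
        if "true_inc" in d:
            kw["true_inc"] = {s: IncidenceParams.from_dict(v) for s, v in d["true_inc"].items()}
        if "true_mrr" in d:
            kw["true_mrr"] = {s: MRRParams.from_dict(v) for s, v in d["true_mrr"].items()}
        if "gompertz" in d:
            kw["gompertz"] = {s: GompertzParams.from_dict(v) for s, v in d["gompertz"].items()}
        for key in ("years", "noise", "seed", "top_age", "aggregate", "step"):
            if key in d:
                kw[key] = tuple(d[key]) if key == "years" else d[key]
        if "groups" in d:
            kw["groups"] = tuple(tuple(g) for g in d["groups"])
        if "denoms" in d:
            kw["denoms"] = {s: tuple(v) for s, v in d["denoms"].items()}
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_truth(config: SyntheticConfig) -> tuple[pd.DataFrame, MortalityTable]:
    """Noise-free group prevalences and the matching mortality table.

    The prevalence of each (sex, year, group) cell is the illness-death ODE
    solution at the true parameters aggregated to that group; there is no
    calendar trend, so all years of a sex share the same true proportions.
    """
    table = MortalityTable.from_gompertz(config.gompertz, config.years, source="synthetic-gompertz")
    groups_df = pd.DataFrame(list(config.groups), columns=["age_lo", "age_hi"])
    rows = []
    for sex in SEXES:
        hazard = table.hazard(sex, t=float(np.mean(config.years)) + 0.5)
        pred = model_group_prevalence(
            config.true_inc[sex],
            config.true_mrr[sex],
            hazard,
            groups_df,
            top_age=config.top_age,
            aggregate=config.aggregate,
            step=config.step,
        )
        for year in config.years:
            for (lo, hi), p, denom in zip(config.groups, pred, config.denoms[sex]):
                rows.append((sex, int(year), int(lo), int(hi), float(p), int(denom)))
    truth = pd.DataFrame(rows, columns=PREV_COLUMNS)
    return validate_groups(truth), table


def add_sampling_noise(
    truth: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Observe each cell through Binomial(denom, prev)/denom sampling."""
    if config.noise != "binomial":
        raise ValueError("add_sampling_noise requires noise mode 'binomial'")
    out = truth.copy()
    n = out["denom"].to_numpy(dtype=np.int64)
    p = out["prev"].to_numpy(dtype=float)
    counts = rng.binomial(n, p)
    out["prev"] = counts / n
    return out


def generate_dataset(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, MortalityTable, dict]:
    """Full synthetic dataset plus a truth manifest for recovery checks."""
    truth, table = generate_truth(config)
    if config.noise == "binomial":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        observed = add_sampling_noise(truth, config, rng)
    else:
        observed = truth.copy()
    manifest = {"config": config.to_dict()}
    return observed, table, manifest
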