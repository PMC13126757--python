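"""All-cause mortality: HMD-style tables, Gompertz hazards, life expectancy.

The pipeline needs the population (all-cause) mortality rate m(a) by single
year of age and sex.  Two sources are supported:

* a mortality table read from a Human Mortality Database "Mx 1x1" style file
  (columns ``Year Age Female Male Total``, terminal age ``110+``) or from a
  plain long CSV (``year,age,sex,mx``);
* a parametric Gompertz hazard ``m(a) = exp(g0 + g1*a)``.

Between integer-age nodes the table is interpolated linearly in log(rate):
hazards act multiplicatively with age, and the rule is exact whenever the
underlying rates follow a Gompertz law.  Calendar time is handled by picking
the nearest tabulated year; the pipeline treats its study window as a single
cross-section, so no interpolation across years is attempted.  Ages beyond
110 are ignored (the HMD ``110+`` group closes the table).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, simpson

__all__ = [
    "GompertzParams",
    "MortalityTable",
    "MortalityParseError",
    "load_mortality",
    "mortality_at",
    "gompertz_mortality",
    "remaining_life_expectancy",
]

log = logging.getLogger(__name__)

MAX_AGE = 110.0
_SEXES = ("female", "male", "total")

# floor applied before taking logs so that an isolated zero rate does not
# poison the log-linear interpolation
_RATE_FLOOR = 1e-10


class MortalityParseError(ValueError):
    """Raised when a mortality file cannot be parsed or validated."""


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard exp(g0 + g1*a): g0 is the log baseline, g1 the slope per year."""

    g0: float
    g1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g0) and math.isfinite(self.g1)):
            raise ValueError("Gompertz parameters must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GompertzParams":
        return cls(g0=float(d["g0"]), g1=float(d["g1"]))


def gompertz_mortality(a, params: GompertzParams):
    """Gompertz central death rate ``exp(g0 + g1*a)`` per person-year."""
    arr = np.asarray(a, dtype=float)
    out = np.exp(params.g0 + params.g1 * arr)
    return out if out.ndim else float(out)


@dataclass
class MortalityTable:
    """All-cause mortality rates on a (year, age, sex) grid.

    ``data`` holds one row per cell with columns ``year`` (int), ``age``
    (int, 0..110 with 110 standing for the HMD terminal group "110+"),
    ``sex`` (female/male/total) and ``mx`` (central death rate per
    person-year).
    """

    data: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        required = {"year", "age", "sex", "mx"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"mortality table missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("mortality table is empty")
        if (self.data["mx"] < 0).any():
            bad = self.data[self.data["mx"] < 0].iloc[0]
            raise ValueError(
                f"negative mortality rate at year={bad['year']} age={bad['age']} sex={bad['sex']}"
            )
        # contiguity of ages per (year, sex)
        for (year, sex), grp in self.data.groupby(["year", "sex"]):
            ages = np.sort(grp["age"].to_numpy())
            if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
                raise ValueError(f"ages not contiguous for year={year} sex={sex}")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def nearest_year(self, t: float) -> int:
        yrs = self.years
        y = int(yrs[np.argmin(np.abs(yrs - t))])
        if abs(y - t) > 0.5:
            log.info("mortality table: using nearest year %d for t=%.2f", y, t)
        return y

    def hazard(self, sex: str, t: float = None) -> Callable:
        """Return a vectorized continuous-age hazard m(a) for one sex.

        Picks the nearest tabulated year to ``t`` (or the only/first year),
        then interpolates log(mx) piecewise-linearly between integer ages.
        """
        if sex not in _SEXES:
            raise ValueError(f"unknown sex {sex!r}; expected one of {_SEXES}")
        year = self.nearest_year(t) if t is not None else int(self.years[0])
        sub = self.data[(self.data["sex"] == sex) & (self.data["year"] == year)]
        if len(sub) == 0:
            raise ValueError(f"no rows for sex={sex} year={year}")
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy(dtype=float)
        logmx = np.log(np.maximum(sub["mx"].to_numpy(dtype=float), _RATE_FLOOR))
        lo, hi = ages[0], ages[-1]

        def m(a):
            arr = np.asarray(a, dtype=float)
            if np.any(arr < 0) or np.any(arr > MAX_AGE):
                raise ValueError(f"age outside [0, {MAX_AGE:g}]")
            out = np.exp(np.interp(np.clip(arr, lo, hi), ages, logmx))
            return out if out.ndim else float(out)

        return m

    def write_csv(self, path) -> None:
        """Write the plain long CSV dialect (year,age,sex,mx)."""
        out = self.data[["year", "age", "sex", "mx"]].copy()
        out.to_csv(path, index=False)

    @classmethod
    def from_gompertz(cls, params_by_sex: dict, years, source: str = "gompertz") -> "MortalityTable":
        """Tabulate Gompertz hazards at integer ages 0..110 for each year.

        ``params_by_sex`` maps 'female'/'male' to :class:`GompertzParams`;
        the 'total' series is the mean of the two sexes' rates.
        """
        ages = np.arange(0, int(MAX_AGE) + 1)
        rows = []
        rates = {s: gompertz_mortality(ages, p) for s, p in params_by_sex.items()}
        if "total" not in rates and {"female", "male"} <= set(rates):
            rates["total"] = 0.5 * (rates["female"] + rates["male"])
        for year in years:
            for sex, mx in rates.items():
                rows.append(
                    pd.DataFrame({"year": int(year), "age": ages, "sex": sex, "mx": mx})
                )
        return cls(data=pd.concat(rows, ignore_index=True), source=source)


def _parse_age(token: str, lineno: int) -> int:
    token = token.strip()
    if token.endswith("+"):
        token = token[:-1]
    try:
        return int(token)
    except ValueError:
        raise MortalityParseError(f"line {lineno}: unparseable age {token!r}") from None


def _parse_rate(token: str, lineno: int, col: str, missing: str):
    token = token.strip()
    if token in (".", "", "NA"):
        if missing == "error":
            raise MortalityParseError(f"line {lineno}: missing value in column {col!r}")
        return None
    try:
        v = float(token)
    except ValueError:
        raise MortalityParseError(f"line {lineno}: unparseable rate {token!r} in column {col!r}") from None
    if v < 0:
        raise MortalityParseError(f"line {lineno}: negative rate {v} in column {col!r}")
    return v


def load_mortality(source: Union[str, Path, io.TextIOBase], missing: str = "error") -> MortalityTable:
    """Parse an HMD Mx-1x1-style file or a plain (year,age,sex,mx) CSV.

    The HMD dialect is whitespace- (or comma-) delimited with a header row
    ``Year Age Female Male Total`` (preamble lines before the header are
    skipped) and accepts the terminal-age sentinel ``110+`` and the missing
    marker ``.``.  ``missing`` is 'error' (default: a missing cell is a parse
    error naming the cell) or 'drop' (the affected cells are omitted).
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        label = str(source)
    else:
        text = source.read()
        label = getattr(source, "name", "<stream>")
    lines = text.splitlines()

    header_idx = None
    for idx, line in enumerate(lines):
        toks = [t.strip().lower() for t in line.replace(",", " ").split()]
        if "year" in toks and "age" in toks:
            header_idx = idx
            header = toks
            break
    if header_idx is None:
        raise MortalityParseError("no header row containing 'Year' and 'Age' found")

    rows = []
    if "sex" in header:  # long CSV dialect
        col = {name: header.index(name) for name in ("year", "age", "sex", "mx")}
        for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
            if not line.strip():
                continue
            toks = [t.strip() for t in line.split(",")]
            if len(toks) < 4:
                raise MortalityParseError(f"line {lineno}: expected 4 fields, got {len(toks)}")
            sex = toks[col["sex"]].lower()
            if sex not in _SEXES:
                raise MortalityParseError(f"line {lineno}: unknown sex {sex!r}")
            mx = _parse_rate(toks[col["mx"]], lineno, "mx", missing)
            if mx is None:
                continue
            rows.append(
                (int(toks[col["year"]]), _parse_age(toks[col["age"]], lineno), sex, mx)
            )
    else:  # HMD wide dialect
        needed = ("year", "age", "female", "male", "total")
        if not all(n in header for n in needed):
            raise MortalityParseError(f"header {header} lacks columns {needed}")
        col = {name: header.index(name) for name in needed}
        for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
            if not line.strip():
                continue
            toks = line.replace(",", " ").split()
            if len(toks) < 5:
                raise MortalityParseError(f"line {lineno}: expected 5 fields, got {len(toks)}")
            year = int(toks[col["year"]])
            age = _parse_age(toks[col["age"]], lineno)
            for sex in ("female", "male", "total"):
                mx = _parse_rate(toks[col[sex]], lineno, sex, missing)
                if mx is None:
                    continue
                rows.append((year, age, sex, mx))

    if not rows:
        raise MortalityParseError(f"no data rows parsed from {label}")
    data = pd.DataFrame(rows, columns=["year", "age", "sex", "mx"])
    return MortalityTable(data=data, source=label)


def mortality_at(a, t: float, sex: str, table: MortalityTable):
    """Rate per person-year at continuous age ``a`` and calendar time ``t``.

    Thin wrapper over :meth:`MortalityTable.hazard` (log-linear in age,
    nearest tabulated year).
    """
    return table.hazard(sex, t)(a)


def remaining_life_expectancy(
    a: float,
    hazard: Callable,
    max_age: float = MAX_AGE,
    step: float = 0.005,
) -> float:
    """Remaining life expectancy e(a) under hazard m, truncated at ``max_age``.

    e(a) = ∫_0^{max_age-a} exp(-∫_0^u m(a+s) ds) du, computed with a
    trapezoidal cumulative hazard and Simpson's rule for the outer integral
    on a grid of spacing ``step`` (default 0.005 year).  Survival mass beyond
    ``max_age`` is discarded, consistent with a table closed at 110.
    """
    if a >= max_age:
        raise ValueError(f"age {a} at or beyond the terminal age {max_age}")
    horizon = max_age - a
    n = max(int(np.ceil(horizon / step)), 2)
    u = np.linspace(0.0, horizon, n + 1)
    h = np.asarray(hazard(a + u), dtype=float)
    if h.shape != u.shape:
        h = np.broadcast_to(h, u.shape)
    if np.any(h < 0) or not np.all(np.isfinite(h)):
        raise ValueError("hazard must be finite and non-negative on [a, max_age]")
    H = cumulative_trapezoid(h, u, initial=0.0)
    S = np.exp(-H)
    return float(simpson(S, x=u))
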