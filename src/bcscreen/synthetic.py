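"""Synthetic calibration inputs: life table, incidence curve, cohorts, scenarios.

The screening evaluation needs three inputs that come from national
registries and censuses rather than from printed tables: an all-cause
female life table, an age-specific breast-cancer incidence curve, and
the age structure of the entry cohort.  This module generates each of
them with the statistical structure the analysis assumes — Gompertz
adult mortality calibrated to a target life expectancy at 40, a smooth
age-increasing (logistic) incidence curve calibrated to an overall rate
per 100,000 women, and multinomial entry-age sampling — so every
downstream stage is testable without external data.

Regional scenarios (incidence multiplier, cohort age weights, screening
coverage) emulate the between-region heterogeneity of a large country:
low-incidence northern regions versus high-incidence southern ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy.optimize import brentq

MAX_AGE = 110
ONSET_MIN_AGE = 30  # onset below 30 is negligible at these incidence levels
INCIDENCE_CAP = 0.02


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities q(age) for females, ages 0..110.

    The table closes at age 110 (q = 1), which bounds the lifetime
    simulation horizon deterministically.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.ndim != 1 or ages.shape != q.shape:
            raise ValueError("ages and q must be matching 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be strictly increasing and contiguous")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if ages[-1] != MAX_AGE or q[-1] != 1.0:
            raise ValueError(f"table must close with q({MAX_AGE}) = 1")
        over40 = ages >= 40
        if np.any(np.diff(q[over40]) < -1e-12):
            raise ValueError("q must be non-decreasing above age 40")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    def q_at(self, age):
        """q for integer age(s); 1 beyond the table."""
        age = np.asarray(age)
        idx = np.clip(age - self.ages[0], 0, len(self.ages) - 1)
        out = self.q[idx]
        return np.where(age > MAX_AGE, 1.0, out)

    def survival_from(self, age: int) -> np.ndarray:
        """S(t) = P(alive t whole years after `age`), t = 0, 1, ..."""
        sel = self.ages >= age
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q[sel])])

    def life_expectancy(self, age: int = 40) -> float:
        """Analytic remaining life expectancy: e(x) = 0.5 + sum_t S(t).

        The half year is the expected part-year lived in the year of
        death, matching the simulator's half-cycle accrual at death.
        """
        s = self.survival_from(age)
        return 0.5 + float(s[1:].sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(), q=df["qx"].to_numpy())


@dataclass(frozen=True)
class IncidenceCurve:
    """Annual probability of clinical breast-cancer onset by age."""

    ages: np.ndarray
    incidence: np.ndarray
    program_start_year: int = 0

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        inc = np.asarray(self.incidence, dtype=float)
        if ages.shape != inc.shape:
            raise ValueError("ages and incidence must match")
        if np.any((inc < 0) | (inc > INCIDENCE_CAP)):
            raise ValueError(f"incidence probabilities must lie in [0, {INCIDENCE_CAP}]")
        if np.any(inc[ages < ONSET_MIN_AGE] > 0):
            raise ValueError(f"incidence must be zero below age {ONSET_MIN_AGE}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "incidence", inc)

    def rate_at(self, age):
        age = np.asarray(age)
        idx = np.clip(age - self.ages[0], 0, len(self.ages) - 1)
        out = self.incidence[idx]
        return np.where((age < self.ages[0]) | (age > self.ages[-1]), 0.0, out)

    def scaled(self, multiplier: float) -> "IncidenceCurve":
        if multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        return IncidenceCurve(self.ages, self.incidence * multiplier, self.program_start_year)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "incidence": self.incidence}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, program_start_year: int = 0) -> "IncidenceCurve":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["incidence"].to_numpy(), program_start_year)


class Scenario(BaseModel):
    """One regional setting: incidence level, entry-age mix, screening uptake."""

    name: str
    incidence_multiplier: float = 1.0
    cohort_age_weights: dict[int, float]
    coverage_override: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.incidence_multiplier <= 0:
            raise ValueError("incidence multiplier must be > 0")
        ages = set(self.cohort_age_weights)
        if not ages or not ages <= set(range(40, 50)):
            raise ValueError("cohort age weights must be over ages 40-49")
        total = sum(self.cohort_age_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cohort age weights sum to {total}, not 1")
        if self.coverage_override is not None and not 0.0 <= self.coverage_override <= 1.0:
            raise ValueError("coverage override must be a probability")
        return self


def uniform_entry_scenario(name: str = "reference", multiplier: float = 1.0,
                           coverage: float | None = None) -> Scenario:
    return Scenario(
        name=name,
        incidence_multiplier=multiplier,
        cohort_age_weights={a: 0.1 for a in range(40, 50)},
        coverage_override=coverage,
    )


def single_age_scenario(age: int = 40, name: str | None = None) -> Scenario:
    """All women enter at one age (the default base-case cohort enters at 40)."""
    return Scenario(name=name or f"entry-at-{age}", cohort_age_weights={age: 1.0})


@dataclass(frozen=True)
class Cohort:
    """Entry ages (40-49) of the simulated women; reproducible from its seed."""

    entry_ages: np.ndarray
    seed: int

    def __post_init__(self):
        ages = np.asarray(self.entry_ages, dtype=np.int16)
        if ages.size < 1:
            raise ValueError("cohort must be nonempty")
        if np.any((ages < 40) | (ages > 49)):
            raise ValueError("entry ages must lie in [40, 49]")
        object.__setattr__(self, "entry_ages", ages)

    @property
    def n(self) -> int:
        return int(self.entry_ages.size)


# ---------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------


def _gompertz_q(a: float, b: float) -> np.ndarray:
    """Annual death probabilities for hazard h(x) = a*exp(b*x), ages 0..110."""
    x = np.arange(0, MAX_AGE + 1, dtype=float)
    cumhaz = (a / b) * (np.exp(b * (x + 1.0)) - np.exp(b * x))
    q = 1.0 - np.exp(-cumhaz)
    q[-1] = 1.0
    return q


def _e40_gompertz(a: float, b: float) -> float:
    q = _gompertz_q(a, b)
    s = np.cumprod(1.0 - q[40:])
    return 0.5 + float(np.concatenate([[1.0], s]) [1:].sum())


def make_life_table(level: float, shape: float = 0.10) -> LifeTable:
    """Gompertz life table scaled so remaining life expectancy at 40 equals `level`.

    Parameters
    ----------
    level : float
        Target e(40) in years (plausible range 30-50).
    shape : float
        Gompertz slope b (log-hazard increase per year of age); 0.10 is
        a typical adult value.
    """
    if not 30.0 <= level <= 50.0:
        raise ValueError(f"target e(40) = {level} outside plausible range [30, 50]")
    if shape <= 0:
        raise ValueError("Gompertz slope must be > 0")
    lo, hi = 1e-12, 1.0
    if not (_e40_gompertz(hi, shape) <= level <= _e40_gompertz(lo, shape)):
        raise ValueError(f"life expectancy {level} unattainable for slope {shape}")
    a = brentq(lambda a_: _e40_gompertz(a_, shape) - level, lo, hi, xtol=1e-15, rtol=1e-13)
    table = LifeTable(ages=np.arange(0, MAX_AGE + 1), q=_gompertz_q(a, shape))
    assert abs(table.life_expectancy(40) - level) < 0.1
    return table


def make_incidence_curve(
    overall_rate_per_100k: float,
    scenario: Scenario | None = None,
    midpoint_age: float = 60.0,
    slope_years: float = 8.0,
) -> IncidenceCurve:
    """Logistic age-increasing onset curve calibrated to an overall rate.

    The curve is scaled so that the mean annual onset probability over
    ages 40-69 equals ``overall_rate_per_100k`` (times the scenario's
    incidence multiplier) per 100,000 women; onset is zero below age 20.
    """
    if overall_rate_per_100k <= 0:
        raise ValueError("overall rate must be > 0")
    multiplier = scenario.incidence_multiplier if scenario is not None else 1.0
    ages = np.arange(0, MAX_AGE + 1)
    shape = 1.0 / (1.0 + np.exp(-(ages - midpoint_age) / slope_years))
    shape[ages < ONSET_MIN_AGE] = 0.0
    window = (ages >= 40) & (ages <= 69)
    target = overall_rate_per_100k / 1e5 * multiplier
    inc = shape * (target / shape[window].mean())
    start = scenario.program_start_year if scenario is not None and hasattr(scenario, "program_start_year") else 0
    curve = IncidenceCurve(ages=ages, incidence=np.minimum(inc, INCIDENCE_CAP), program_start_year=start)
    achieved = float(curve.incidence[window].mean())
    if abs(achieved - target) > 0.01 * target:
        raise ValueError("incidence calibration failed (curve hit its cap)")
    return curve


def make_cohort(n: int, scenario: Scenario, seed: int) -> Cohort:
    """Draw `n` entry ages from the scenario's age weights, reproducibly."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ages = np.array(sorted(scenario.cohort_age_weights), dtype=np.int16)
    w = np.array([scenario.cohort_age_weights[int(a)] for a in ages])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xC040,)))
    entry = rng.choice(ages, size=n, p=w / w.sum())
    return Cohort(entry_ages=entry, seed=seed)


def make_region_scenarios() -> list[Scenario]:
    """Packaged synthetic regional scenarios spanning low to high incidence.

    Coverage overrides stay inside the plausible opportunistic-uptake
    range (10-30%); the age mixes tilt slightly younger where incidence
    is high, emulating regional demographic differences.
    """
    young_tilt = {a: w for a, w in zip(range(40, 50), np.linspace(0.14, 0.06, 10) / np.linspace(0.14, 0.06, 10).sum())}
    old_tilt = {a: w for a, w in zip(range(40, 50), np.linspace(0.06, 0.14, 10) / np.linspace(0.06, 0.14, 10).sum())}
    uniform = {a: 0.1 for a in range(40, 50)}
    return [
        Scenario(name="low-incidence", incidence_multiplier=0.5,
                 cohort_age_weights=young_tilt, coverage_override=0.10),
        Scenario(name="lower-middle-incidence", incidence_multiplier=0.8,
                 cohort_age_weights=uniform, coverage_override=0.15),
        Scenario(name="reference", incidence_multiplier=1.0,
                 cohort_age_weights=uniform, coverage_override=0.18),
        Scenario(name="upper-middle-incidence", incidence_multiplier=1.3,
                 cohort_age_weights=old_tilt, coverage_override=0.24),
        Scenario(name="high-incidence", incidence_multiplier=1.5,
                 cohort_age_weights=old_tilt, coverage_override=0.30),
    ]


def default_life_table() -> LifeTable:
    """The default synthetic female life table: e(40) = 40 years."""
    return make_life_table(level=40.0, shape=0.10)


def default_incidence_curve(scenario: Scenario | None = None) -> IncidenceCurve:
    """Default onset curve: 50 cases per 100,000 women-years over ages 40-69."""
    return make_incidence_curve(50.0, scenario=scenario)
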