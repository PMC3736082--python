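"""Screening strategies, attendance, test performance and stage at detection.

Seven strategies are compared for women entering at ages 40-49:

====  =========================================================
A     usual care — opportunistic SFM only
B     organised annual SFM, ages 40-69
C     organised SFM every 2 years, ages 40-69
D     organised annual FFDM, ages 40-69
E     organised FFDM every 2 years, ages 40-69
F     age-targeted: annual FFDM 40-49, then annual SFM 50-69
G     age-targeted: annual FFDM 40-49, then biennial SFM 50-69
====  =========================================================

No screening is offered below 40 or above 69.  A woman's first attended
screen is her "prevalence" round (higher recall rate); all later
attended screens are "incidence" rounds.  Recalled women undergo repeat
imaging, a fraction proceed to fine-needle aspiration and a smaller
fraction to surgical biopsy.  For FFDM in women under 50, the odds of a
late-stage (S3/S4) diagnosis are shifted by the diagnostic downstage
odds ratio; the DCIS share of screen-detected disease ramps up over the
first decade of an organised programme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from . import natural_history as nh
from .parameters import ParameterSet, StageDistribution, TestPerformance

SCREEN_MIN_AGE, SCREEN_MAX_AGE = 40, 69


class ScheduleRow(BaseModel):
    age_from: int
    age_to: int
    modality: Literal["SFM", "FFDM"]
    interval_years: Literal[1, 2]

    @model_validator(mode="after")
    def _check(self) -> "ScheduleRow":
        if self.age_from < SCREEN_MIN_AGE or self.age_to > SCREEN_MAX_AGE:
            raise ValueError(f"screening must stay within ages {SCREEN_MIN_AGE}-{SCREEN_MAX_AGE}")
        if self.age_from > self.age_to:
            raise ValueError("age_from must be <= age_to")
        return self


class StrategySpec(BaseModel):
    """A screening schedule plus its participation source.

    Participation resolves at run time from the coverage block of the
    parameter set (``opportunistic`` for usual care, ``organized`` for
    programme strategies) unless a fixed probability is given.
    """

    id: str
    label: str = ""
    schedule: list[ScheduleRow] = []
    participation_source: Literal["opportunistic", "organized", "fixed"] = "organized"
    participation: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "StrategySpec":
        if self.participation_source == "fixed":
            if self.participation is None or not 0.0 <= self.participation <= 1.0:
                raise ValueError("fixed participation requires a probability")
        if not self.schedule and self.participation_source == "organized":
            raise ValueError("an empty schedule means usual care: use opportunistic participation")
        return self

    def resolve_participation(self, params: ParameterSet) -> float:
        if self.participation_source == "fixed":
            return float(self.participation)
        return getattr(params.coverage, self.participation_source).point_estimate


def default_strategies() -> dict[str, StrategySpec]:
    """The seven packaged strategies A-G."""
    def rows(*r):
        return [ScheduleRow(age_from=a, age_to=b, modality=m, interval_years=i) for a, b, m, i in r]

    return {
        "A": StrategySpec(id="A", label="usual care", schedule=[],
                          participation_source="opportunistic"),
        "B": StrategySpec(id="B", label="SFM annual", schedule=rows((40, 69, "SFM", 1))),
        "C": StrategySpec(id="C", label="SFM every 2 years", schedule=rows((40, 69, "SFM", 2))),
        "D": StrategySpec(id="D", label="FFDM annual", schedule=rows((40, 69, "FFDM", 1))),
        "E": StrategySpec(id="E", label="FFDM every 2 years", schedule=rows((40, 69, "FFDM", 2))),
        "F": StrategySpec(id="F", label="FFDM (<50) + SFM (50-69) annual",
                          schedule=rows((40, 49, "FFDM", 1), (50, 69, "SFM", 1))),
        "G": StrategySpec(id="G", label="FFDM (<50) annual + SFM (50-69) biennial",
                          schedule=rows((40, 49, "FFDM", 1), (50, 69, "SFM", 2))),
    }


def scheduled_modality(strategy: StrategySpec, age: int,
                       last_screen_age: int | None = None) -> str | None:
    """Modality due this year under the organised schedule, or None.

    Biennial rows are due when at least the interval has elapsed since
    the last attended screen.  Nothing is due above 69 or below 40.
    """
    if age < SCREEN_MIN_AGE:
        raise ValueError("screening schedules start at age 40")
    if age > SCREEN_MAX_AGE:
        return None
    for row in strategy.schedule:
        if row.age_from <= age <= row.age_to:
            if row.interval_years == 1:
                return row.modality
            if last_screen_age is None or age - last_screen_age >= row.interval_years:
                return row.modality
    return None


def offered_modality(strategy: StrategySpec, age: int,
                     last_screen_age: int | None = None) -> str | None:
    """Modality actually offered this year: the organised schedule, or
    opportunistic SFM for empty-schedule (usual care) strategies."""
    if strategy.schedule:
        return scheduled_modality(strategy, age, last_screen_age)
    return "SFM" if SCREEN_MIN_AGE <= age <= SCREEN_MAX_AGE else None


def attends(participation: float, rng: np.random.Generator, size=None):
    """Bernoulli attendance draw(s)."""
    if not 0.0 <= participation <= 1.0:
        raise ValueError("participation must be a probability")
    u = rng.random() if size is None else rng.random(size)
    return u < participation


@dataclass(frozen=True)
class ScreenEvent:
    """Outcome of one attended screen."""

    age: int
    modality: str
    round: str  # prevalence | incidence
    outcome: str  # true_positive | false_negative | false_positive_recall | negative
    workup: frozenset = frozenset()

    def __post_init__(self):
        if self.workup and self.outcome in ("negative", "false_negative"):
            raise ValueError("work-up is only defined for recalls and detections")


def screen_outcome(state: nh.HealthState, modality: str, age: int,
                   tp: TestPerformance, round: str,
                   rng: np.random.Generator) -> ScreenEvent:
    """Resolve one attended screen for one woman.

    Undiagnosed disease is detected with the modality/age-band
    sensitivity; healthy women are recalled falsely at the round- and
    modality-specific recall rate, and recalled women undergo repeat
    imaging with fractions proceeding to FNA and surgical biopsy.
    """
    if not SCREEN_MIN_AGE <= age <= SCREEN_MAX_AGE:
        raise ValueError(f"screen at age {age} violates the 40-69 schedule contract")
    if not state.alive:
        raise ValueError("cannot screen a dead woman")
    diseased = state.compartment in nh.CANCER_COMPARTMENTS and state.detection_mode == nh.DETECT_NONE
    if diseased:
        if rng.random() < tp.sensitivity_value(modality, age):
            return ScreenEvent(age, modality, round, "true_positive",
                               frozenset({"repeat_imaging", "surgical_biopsy"}))
        return ScreenEvent(age, modality, round, "false_negative")
    if rng.random() < tp.recall_rate[modality][round].point_estimate:
        workup = {"repeat_imaging"}
        if rng.random() < tp.fna_fraction.point_estimate:
            workup.add("FNA")
        if rng.random() < tp.biopsy_fraction.point_estimate:
            workup.add("surgical_biopsy")
        return ScreenEvent(age, modality, round, "false_positive_recall", frozenset(workup))
    return ScreenEvent(age, modality, round, "negative")


def screen_stage_probs(sd: StageDistribution, modality: str, age: int,
                       downstage_or: float, dcis_multiplier: float = 1.0) -> np.ndarray:
    """Stage-at-detection probabilities (DCIS, S1..S4) for a screen detection.

    The DCIS share is the base share times the programme-time ramp
    multiplier; the remainder is split by the invasive-conditional
    fractions.  For FFDM under age 50 the early (DCIS+S1+S2) versus
    late (S3+S4) odds are shifted by the downstage odds ratio
    (odds_early' = odds_early / OR), renormalising within each group.
    """
    if downstage_or <= 0:
        raise ValueError("downstage odds ratio must be > 0")
    p_dcis = min(sd.dcis.point_estimate * dcis_multiplier, 0.5)
    inv = sd.invasive_conditional()
    p = np.concatenate([[p_dcis], (1.0 - p_dcis) * inv])
    if modality == "FFDM" and age < 50 and downstage_or != 1.0:
        early = p[:3].sum()
        odds = early / (1.0 - early)
        odds_new = odds / downstage_or
        early_new = odds_new / (1.0 + odds_new)
        p = np.concatenate([p[:3] * (early_new / early),
                            p[3:] * ((1.0 - early_new) / (1.0 - early))])
    assert abs(p.sum() - 1.0) < 1e-9
    return p


def screen_detected_stage(sd: StageDistribution, modality: str, age: int,
                          downstage_or: float, dcis_multiplier: float,
                          rng: np.random.Generator, size=None):
    """Draw stage compartment code(s) for screen-detected disease."""
    p = screen_stage_probs(sd, modality, age, downstage_or, dcis_multiplier)
    u = rng.random() if size is None else rng.random(size)
    codes = nh.draw_stage(p, u)
    return int(codes[0]) if size is None else codes


def mark_overdiagnosis(p: float, rng: np.random.Generator, size=None):
    """Bernoulli flag(s) for screen-detected disease that would never surface."""
    if not 0.0 <= p <= 0.30:
        raise ValueError(f"overdiagnosis probability {p} outside plausible range [0, 0.30]")
    u = rng.random() if size is None else rng.random(size)
    return u < p
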