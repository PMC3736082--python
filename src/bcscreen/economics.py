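"""Cost and utility accrual, discounting and half-cycle correction.

Costs are 2010 Brazilian reais (R$) from the public-payer perspective:
screening tests, recall work-up, diagnostic biopsy, staging, and
aggregate first-year / subsequent-year treatment costs by stage.
Utilities are SF-6D weights; a false-positive recall replaces the
healthy weight for that cycle with the slightly lower false-positive
weight.  Accruals are discounted at mid-cycle time (t + 0.5) when the
half-cycle correction is on — the individual-level analogue of the
cohort half-cycle rule — and a woman who dies within a cycle accrues
half a cycle of her pre-death state's cost and utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import natural_history as nh
from .parameters import CostTable, UtilityTable
from .screening import ScreenEvent

EARLY_COMPARTMENTS = (nh.DCIS, nh.S1, nh.S2)  # "early" for staging costs


def discount(value: float, years_from_start: float, rate: float) -> float:
    """Present value of an amount accruing ``years_from_start`` years out."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return value / (1.0 + rate) ** years_from_start


def false_positive_utility(u_healthy: float, u_disease_reference: float,
                           episode_months: float) -> float:
    """Utility weight for a healthy woman with a false-positive episode.

    The annual weight is the healthy weight minus the disutility gap to
    the non-metastatic reference, pro-rated over the episode length,
    rounded to 3 decimals: 0.80 healthy, 0.77 reference and a 2-month
    episode give 0.795.
    """
    for name, u in (("u_healthy", u_healthy), ("u_disease_reference", u_disease_reference)):
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0.0 <= episode_months <= 12.0:
        raise ValueError("episode length must lie in [0, 12] months")
    return round(u_healthy - (u_healthy - u_disease_reference) * episode_months / 12.0, 3)


def _stage_key(compartment: int) -> str:
    if compartment == nh.ADVANCED:
        return "S4"
    return nh.STAGE_KEYS[compartment - nh.DCIS]


def cycle_cost(state: nh.HealthState, events: list, costs: CostTable,
               complication_cost: float = 509.0) -> float:
    """Total undiscounted cost accrued by one woman in one cycle.

    ``events`` may contain :class:`ScreenEvent` objects and the string
    tokens ``"diagnosis"`` (biopsy + staging work-up in the diagnosis
    cycle) and ``"complication"`` (one treatment-complication episode).
    Dead states accrue nothing.
    """
    if state.compartment in (nh.DEAD_BC, nh.DEAD_OTHER):
        return 0.0
    total = 0.0
    if state.compartment in nh.CANCER_COMPARTMENTS:
        key = _stage_key(state.compartment)
        table = costs.first_year if state.years_since_diagnosis == 0 else costs.subsequent_year
        total += table[key].point_estimate
    for ev in events:
        if isinstance(ev, ScreenEvent):
            total += costs.modality_cost(ev.modality) + costs.medical_visit.point_estimate
            if ev.outcome in ("false_positive_recall", "true_positive"):
                total += costs.recall_cost(ev.modality)
            if "surgical_biopsy" in ev.workup and ev.outcome != "true_positive":
                total += costs.biopsy.point_estimate
        elif ev == "diagnosis":
            total += costs.biopsy.point_estimate
            staging = (costs.staging_early if state.compartment in EARLY_COMPARTMENTS
                       else costs.staging_advanced)
            total += staging.point_estimate
        elif ev == "complication":
            total += complication_cost
        else:
            raise ValueError(f"unknown event {ev!r}")
    return total


def cycle_utility(state: nh.HealthState, events: list, utilities: UtilityTable,
                  complication_disutility: float = 0.02,
                  endocrine_years: int = 5) -> float:
    """Utility weight for one woman in one cycle (0 when dead).

    Healthy women score the healthy weight, or the false-positive weight
    if recalled falsely this cycle.  Diagnosed women score by treatment
    phase: chemotherapy weight in the diagnosis year, endocrine weight
    while on endocrine therapy, follow-up weight otherwise; advanced
    disease scores the advanced weight throughout.  A complication this
    cycle subtracts a small decrement.
    """
    c = state.compartment
    if c in (nh.DEAD_BC, nh.DEAD_OTHER):
        return 0.0
    fp_recall = any(isinstance(ev, ScreenEvent) and ev.outcome == "false_positive_recall"
                    for ev in events)
    if c == nh.HEALTHY:
        u = (utilities.healthy_false_positive if fp_recall else utilities.healthy).point_estimate
    elif c in (nh.S4, nh.ADVANCED):
        u = utilities.s4.point_estimate
    else:
        on_chemo_year = state.years_since_diagnosis == 0 and state.treatments & nh.T_CHEMO
        on_endocrine = (state.treatments & nh.T_ENDOCRINE
                        and state.years_since_diagnosis < endocrine_years)
        if c == nh.S3:
            if on_chemo_year:
                u = utilities.s3_chemo.point_estimate
            elif on_endocrine:
                u = utilities.s3_endocrine.point_estimate
            else:
                u = utilities.followup_nonmetastatic.point_estimate
        else:  # DCIS, S1, S2
            if on_chemo_year:
                u = utilities.early_chemo.point_estimate
            elif on_endocrine:
                u = utilities.early_endocrine.point_estimate
            else:
                u = utilities.followup_nonmetastatic.point_estimate
    if "complication" in [ev for ev in events if isinstance(ev, str)]:
        u -= complication_disutility
    return max(u, 0.0)


@dataclass
class AccrualLedger:
    """Per-cycle undiscounted accruals for one woman (or one cohort mean)."""

    cycles: list = field(default_factory=list)
    costs: list = field(default_factory=list)
    utilities: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def add(self, cycle: int, cost: float, utility: float, events=()) -> None:
        if not 0.0 <= utility <= 1.0:
            raise ValueError("per-cycle utility weight must lie in [0, 1]")
        self.cycles.append(cycle)
        self.costs.append(cost)
        self.utilities.append(utility)
        self.events.append(tuple(events))

    def totals(self, rate: float, correction_on: bool = True) -> tuple[float, float]:
        """(discounted cost, discounted QALY) over the ledger."""
        t = np.asarray(self.cycles, dtype=float)
        offset = 0.5 if correction_on else 0.0
        df = (1.0 + rate) ** -(t + offset)
        return (float(np.dot(self.costs, df)), float(np.dot(self.utilities, df)))


def accrue_with_half_cycle(ledger: AccrualLedger, correction_on: bool,
                           rate: float) -> tuple[float, float]:
    """Discounted (cost, QALY) totals; mid-cycle timing when correction is on."""
    return ledger.totals(rate, correction_on)
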