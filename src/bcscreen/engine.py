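"""Annual-cycle micro-simulation of whole cohorts under each screening strategy.

Each woman is followed from her entry age (40-49) to death or age 110 in
1-year cycles.  Within a cycle events resolve in a fixed order — other-
cause death, breast-cancer death, recurrence, screening, clinical onset
and detection, complications, then accrual — so runs are bit-reproducible
from (master seed, cohort, parameter set, tables).

Random numbers are counter-based: every (purpose, cycle) pair has its
own stream keyed by the master seed, and woman *i* always consumes
element *i* of that stream.  With common random numbers (CRN, the
default) the streams are shared across strategies, so two strategies
differ only through the draws they actually use and paired differences
between strategies have much lower Monte Carlo variance.

The implementation is vectorised over the cohort; a single-woman
trajectory with a full per-cycle ledger is available through
:func:`simulate_individual`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import zlib

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import natural_history as nh
from .economics import AccrualLedger
from .parameters import ParameterSet
from .screening import StrategySpec, SCREEN_MIN_AGE, SCREEN_MAX_AGE
from .synthetic import Cohort, IncidenceCurve, LifeTable

# RNG purposes (stream keys)
(P_OTHER, P_BCDEATH, P_REC, P_RECTYPE, P_ATTEND, P_ONSET, P_DETECT, P_STAGE,
 P_SUBTYPE, P_OVERDX, P_RECALL, P_FNA, P_BIOPSY, P_CCHEMO, P_CENDO) = range(15)

_CANCER = np.array(nh.CANCER_COMPARTMENTS)
_RECURRABLE = np.array(nh.RECURRABLE)


class SimulationSettings(BaseModel):
    n_individuals: int = 10_000
    master_seed: int = 0
    common_random_numbers: bool = True
    max_age: int = 110
    cycle_years: int = 1
    trace: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SimulationSettings":
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.cycle_years != 1:
            raise ValueError("the cycle length is fixed at 1 year")
        if self.master_seed < 0:
            raise ValueError("master_seed must be >= 0")
        return self


@dataclass
class StrategyResult:
    """Cohort outcome of one strategy: mean discounted cost and QALY plus counts."""

    strategy_id: str
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    mean_life_years: float
    event_counts: dict
    costs: np.ndarray = field(repr=False)
    qalys: np.ndarray = field(repr=False)
    life_years: np.ndarray = field(repr=False)
    cycle_summary: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "strategy": self.strategy_id, "n": self.n,
            "cost": self.mean_cost, "qaly": self.mean_qaly,
            "se_cost": self.se_cost, "se_qaly": self.se_qaly,
            "life_years": self.mean_life_years,
        }


@dataclass
class Trajectory:
    """One woman's simulated path with its per-cycle accrual ledger."""

    entry_age: int
    frame: pd.DataFrame
    ledger: AccrualLedger
    discounted_cost: float
    discounted_qaly: float
    life_years: float


def _uniforms(master_seed: int, strat_key: int, purpose: int, t: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(strat_key, purpose, t))
    return np.random.default_rng(ss).random(n)


def _due_modality(strategy: StrategySpec, age: np.ndarray,
                  last_screen_age: np.ndarray) -> np.ndarray:
    """0 = none, 1 = SFM, 2 = FFDM, vectorised over women."""
    due = np.zeros(age.shape, dtype=np.int8)
    in_window = (age >= SCREEN_MIN_AGE) & (age <= SCREEN_MAX_AGE)
    if not strategy.schedule:
        due[in_window] = 1  # opportunistic SFM under usual care
        return due
    for row in strategy.schedule:
        band = in_window & (age >= row.age_from) & (age <= row.age_to)
        if row.interval_years > 1:
            band &= (last_screen_age < 0) | (age - last_screen_age >= row.interval_years)
        due[band] = 1 if row.modality == "SFM" else 2
    return due


def run_strategy(
    cohort: Cohort,
    strategy: StrategySpec,
    params: ParameterSet,
    life_table: LifeTable,
    incidence: IncidenceCurve,
    settings: SimulationSettings,
    participation_override: float | None = None,
) -> StrategyResult:
    """Simulate the full cohort under one strategy and aggregate outcomes."""
    n = cohort.n
    entry = cohort.entry_ages.astype(np.int64)
    seed = settings.master_seed
    strat_key = 0 if settings.common_random_numbers else 1 + (zlib.crc32(strategy.id.encode()) & 0xFFFF)

    participation = (participation_override if participation_override is not None
                     else strategy.resolve_participation(params))

    # --- parameter scalars / lookup tables ---------------------------
    econ = params.econ
    rate = econ.discount_rate.point_estimate
    hcc = econ.half_cycle_correction
    tp = params.test_performance
    nhp = params.nat_hist
    tr = params.treatment
    ct = params.costs
    ut = params.utilities

    sens = {m: {b: tp.sensitivity[m][b].point_estimate for b in ("40-49", "50-59", "60-69")}
            for m in ("SFM", "FFDM")}
    recall = {m: {r: tp.recall_rate[m][r].point_estimate for r in ("prevalence", "incidence")}
              for m in ("SFM", "FFDM")}
    clin_cum = np.cumsum(params.stage_clinical.probabilities())
    sub_prev = nhp.subtype_prevalence
    sub_cum = np.cumsum([sub_prev[k] for k in ("LumA", "LumB", "HER2", "TN")])
    p_overdx = nhp.overdiagnosis.point_estimate
    downstage_or = tr.downstage_or_ffdm_under50.point_estimate
    p_comp_chemo = tr.complication_annual["chemo"].point_estimate
    p_comp_endo = tr.complication_annual["endocrine"].point_estimate
    endocrine_years = tr.endocrine_years

    first_cost = np.array([ct.first_year[k].point_estimate for k in nh.STAGE_KEYS])
    sub_cost = np.array([ct.subsequent_year[k].point_estimate for k in nh.STAGE_KEYS])
    modality_cost = np.array([0.0, ct.sfm.point_estimate, ct.ffdm.point_estimate])
    recall_cost = np.array([0.0, ct.recall_sfm.point_estimate, ct.recall_ffdm.point_estimate])
    visit_cost = ct.medical_visit.point_estimate
    biopsy_cost = ct.biopsy.point_estimate
    staging_early = ct.staging_early.point_estimate
    staging_adv = ct.staging_advanced.point_estimate

    u_healthy = ut.healthy.point_estimate
    u_fp = ut.healthy_false_positive.point_estimate
    u_followup = ut.followup_nonmetastatic.point_estimate
    u_early_endo = ut.early_endocrine.point_estimate
    u_early_chemo = ut.early_chemo.point_estimate
    u_s3_endo = ut.s3_endocrine.point_estimate
    u_s3_chemo = ut.s3_chemo.point_estimate
    u_s4 = ut.s4.point_estimate

    from .screening import screen_stage_probs  # local import avoids cycle at module load

    # --- state arrays ------------------------------------------------
    comp = np.full(n, nh.HEALTHY, dtype=np.int8)
    years_dx = np.zeros(n, dtype=np.int16)
    detect = np.zeros(n, dtype=np.int8)
    overdx = np.zeros(n, dtype=bool)
    subtype = np.zeros(n, dtype=np.int8)
    treat = np.zeros(n, dtype=np.uint8)
    ever_scr = np.zeros(n, dtype=bool)
    last_scr = np.full(n, -1, dtype=np.int64)

    disc_cost = np.zeros(n)
    disc_qaly = np.zeros(n)
    life_years = np.zeros(n)

    counts = {
        "screens": 0, "recalls": 0, "false_positive_recalls": 0, "fna": 0,
        "surgical_biopsies": 0, "cancers": 0, "screen_detected": 0,
        "false_negatives": 0, "overdiagnosed": 0, "recurrences_local": 0,
        "recurrences_regional_systemic": 0, "bc_deaths": 0, "other_deaths": 0,
    }
    cancers_by_stage = np.zeros(5, dtype=np.int64)
    screen_by_stage = np.zeros(5, dtype=np.int64)
    trace_rows: list[dict] = []
    cycle_cost_sum: list[float] = []
    cycle_util_sum: list[float] = []
    cycle_alive: list[int] = []

    max_cycles = settings.max_age - int(entry.min()) + 1
    for t in range(max_cycles + 1):
        alive = comp < nh.DEAD_BC
        if not alive.any():
            break
        age = entry + t
        U = lambda p: _uniforms(seed, strat_key, p, t, n)  # noqa: E731

        # 1) other-cause death
        q = life_table.q_at(age)
        die_o = alive & (U(P_OTHER) < q)

        # 2) breast-cancer death
        p_bcd = nh.bc_death_hazard(comp, detect, subtype, treat, overdx, params)
        die_bc = alive & ~die_o & np.isin(comp, _CANCER) & (U(P_BCDEATH) < p_bcd)
        died = die_o | die_bc
        surv = alive & ~died

        # 3) recurrence
        p_rec = nh.recurrence_hazard(comp, treat, overdx, params)
        rec = surv & np.isin(comp, _RECURRABLE) & (U(P_REC) < p_rec)
        local_frac = np.zeros(n)
        for c in nh.RECURRABLE:
            key = nh.STAGE_KEYS[c - nh.DCIS]
            local_frac[comp == c] = nhp.recurrence_local_fraction[key].point_estimate
        local = rec & (U(P_RECTYPE) < local_frac)
        regsys = rec & ~local
        years_dx[local] = 0  # local: re-enter the same stage's treated pathway
        if regsys.any():
            comp[regsys] = nh.ADVANCED
            years_dx[regsys] = 0
            hr_pos = np.isin(subtype, nh.HORMONE_POSITIVE)
            treat[regsys] = (nh.T_CHEMO | np.where(hr_pos[regsys], nh.T_ENDOCRINE, 0)).astype(np.uint8)
        counts["recurrences_local"] += int(local.sum())
        counts["recurrences_regional_systemic"] += int(regsys.sum())

        # 4) screening offer and attendance
        due = np.where(surv, _due_modality(strategy, age, last_scr), 0)
        att = surv & (due > 0) & (U(P_ATTEND) < participation)
        first_round = att & ~ever_scr
        ever_scr |= att
        last_scr[att] = age[att]
        healthy_at_screen = surv & (comp == nh.HEALTHY)
        event_cost = np.zeros(n)
        event_cost[att] += modality_cost[due[att]] + visit_cost
        counts["screens"] += int(att.sum())

        # 5) clinical onset and detection routing
        p_on = incidence.rate_at(age)
        onset = surv & (comp == nh.HEALTHY) & (U(P_ONSET) < p_on)
        sens_band = np.where(age < 50, 0, np.where(age < 60, 1, 2))
        sens_vec = np.zeros(n)
        for m_code, m in ((1, "SFM"), (2, "FFDM")):
            for b_idx, b in enumerate(("40-49", "50-59", "60-69")):
                sel = (due == m_code) & (sens_band == b_idx)
                sens_vec[sel] = sens[m][b]
        detected = onset & att & (U(P_DETECT) < sens_vec)
        missed = onset & att & ~detected
        counts["false_negatives"] += int(missed.sum())
        clin_dx = onset & ~detected

        u_stage = U(P_STAGE)
        new_stage = np.zeros(n, dtype=np.int8)
        if clin_dx.any():
            new_stage[clin_dx] = nh.DCIS + np.searchsorted(
                clin_cum, u_stage[clin_dx], side="right").clip(0, 4)
        if detected.any():
            ramp = nh.dcis_ramp_multiplier(t, nhp.dcis_ramp_years, nhp.dcis_plateau_multiplier)
            p_scr = screen_stage_probs(params.stage_screen, "SFM", 55, downstage_or, ramp)
            p_scr_young = screen_stage_probs(params.stage_screen, "FFDM", 45, downstage_or, ramp)
            cum_scr, cum_young = np.cumsum(p_scr), np.cumsum(p_scr_young)
            ffdm_young = detected & (due == 2) & (age < 50)
            plain = detected & ~ffdm_young
            new_stage[plain] = nh.DCIS + np.searchsorted(
                cum_scr, u_stage[plain], side="right").clip(0, 4)
            new_stage[ffdm_young] = nh.DCIS + np.searchsorted(
                cum_young, u_stage[ffdm_young], side="right").clip(0, 4)

        new_dx = clin_dx | detected
        if new_dx.any():
            comp[new_dx] = new_stage[new_dx]
            years_dx[new_dx] = 0
            detect[new_dx] = np.where(detected[new_dx], nh.DETECT_SCREEN, nh.DETECT_CLINICAL)
            subtype[new_dx] = nh.SUB_LUMA + np.searchsorted(
                sub_cum, U(P_SUBTYPE)[new_dx], side="right").clip(0, 3)
            treat[new_dx] = nh.assign_treatments(comp[new_dx], subtype[new_dx])
            od = detected & (U(P_OVERDX) < p_overdx)
            overdx |= od
            counts["overdiagnosed"] += int(od.sum())
            early = np.isin(comp, (nh.DCIS, nh.S1, nh.S2))
            event_cost[new_dx] += biopsy_cost + np.where(early[new_dx], staging_early, staging_adv)
            event_cost[detected] += recall_cost[due[detected]]  # true-positive recall work-up
            counts["recalls"] += int(detected.sum())
            counts["cancers"] += int(new_dx.sum())
            counts["screen_detected"] += int(detected.sum())
            np.add.at(cancers_by_stage, nh.stage_index(comp[new_dx]), 1)
            np.add.at(screen_by_stage, nh.stage_index(comp[detected]), 1)

        # false-positive recalls among healthy attendees without onset
        fp_cand = att & healthy_at_screen & ~onset
        rate_vec = np.zeros(n)
        for m_code, m in ((1, "SFM"), (2, "FFDM")):
            sel = fp_cand & (due == m_code)
            rate_vec[sel] = np.where(first_round[sel], recall[m]["prevalence"], recall[m]["incidence"])
        fp = fp_cand & (U(P_RECALL) < rate_vec)
        event_cost[fp] += recall_cost[due[fp]]
        fna = fp & (U(P_FNA) < tp.fna_fraction.point_estimate)
        sbio = fp & (U(P_BIOPSY) < tp.biopsy_fraction.point_estimate)
        event_cost[sbio] += biopsy_cost
        counts["recalls"] += int(fp.sum())
        counts["false_positive_recalls"] += int(fp.sum())
        counts["fna"] += int(fna.sum())
        counts["surgical_biopsies"] += int(sbio.sum())

        # 6) treatment complications
        diagnosed = surv & np.isin(comp, _CANCER)
        on_chemo = diagnosed & (years_dx == 0) & ((treat & nh.T_CHEMO) > 0)
        on_endo = diagnosed & ((treat & nh.T_ENDOCRINE) > 0) & (years_dx < endocrine_years)
        complication = (on_chemo & (U(P_CCHEMO) < p_comp_chemo)) | (on_endo & (U(P_CENDO) < p_comp_endo))
        event_cost[complication] += tr.complication_cost

        # 7) accrual (died women: half a cycle of pre-death state, no events)
        stage_idx = nh.stage_index(comp).clip(0, 4)
        in_cancer = np.isin(comp, _CANCER)
        state_cost = np.where(
            in_cancer, np.where(years_dx == 0, first_cost[stage_idx], sub_cost[stage_idx]), 0.0)

        util = np.full(n, u_healthy)
        util[fp] = u_fp
        adv = (comp == nh.S4) | (comp == nh.ADVANCED)
        util[adv] = u_s4
        early_c = np.isin(comp, (nh.DCIS, nh.S1, nh.S2))
        s3 = comp == nh.S3
        chemo_year = in_cancer & (years_dx == 0) & ((treat & nh.T_CHEMO) > 0)
        endo_active = in_cancer & ((treat & nh.T_ENDOCRINE) > 0) & (years_dx < endocrine_years)
        util[early_c] = u_followup
        util[early_c & endo_active] = u_early_endo
        util[early_c & chemo_year] = u_early_chemo
        util[s3] = u_followup
        util[s3 & endo_active] = u_s3_endo
        util[s3 & chemo_year] = u_s3_chemo
        util[complication] -= tr.complication_disutility
        np.clip(util, 0.0, 1.0, out=util)

        w = np.where(died, 0.5, 1.0) * alive
        df = (1.0 + rate) ** -(t + (0.5 if hcc else 0.0))
        cycle_costs = event_cost * surv + state_cost * w
        cycle_utils = util * w
        disc_cost += cycle_costs * df
        disc_qaly += cycle_utils * df
        life_years += w

        cycle_cost_sum.append(float(cycle_costs.sum()))
        cycle_util_sum.append(float(cycle_utils.sum()))
        cycle_alive.append(int(alive.sum()))

        if settings.trace:
            for i in range(n):
                if alive[i]:
                    trace_rows.append({
                        "woman": i, "cycle": t, "age": int(age[i]),
                        "compartment": nh.COMPARTMENT_NAMES[comp[i]],
                        "screened": bool(att[i]), "fp_recall": bool(fp[i]),
                        "diagnosed": bool(new_dx[i]), "died": bool(died[i]),
                        "cost": float(cycle_costs[i]), "utility": float(cycle_utils[i]),
                    })

        # 8) finalise deaths and age the diagnosed
        comp[die_bc] = nh.DEAD_BC
        comp[die_o] = nh.DEAD_OTHER
        counts["bc_deaths"] += int(die_bc.sum())
        counts["other_deaths"] += int(die_o.sum())
        years_dx[surv & np.isin(comp, _CANCER)] += 1

    counts["cancers_by_stage"] = {k: int(v) for k, v in zip(nh.STAGE_KEYS, cancers_by_stage)}
    counts["screen_detected_by_stage"] = {k: int(v) for k, v in zip(nh.STAGE_KEYS, screen_by_stage)}
    summary = pd.DataFrame({
        "cycle": np.arange(len(cycle_cost_sum)),
        "mean_cost": np.array(cycle_cost_sum) / n,
        "mean_utility": np.array(cycle_util_sum) / n,
        "alive": cycle_alive,
    })
    return StrategyResult(
        strategy_id=strategy.id, n=n,
        mean_cost=float(disc_cost.mean()), mean_qaly=float(disc_qaly.mean()),
        se_cost=float(disc_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(disc_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_life_years=float(life_years.mean()),
        event_counts=counts, costs=disc_cost, qalys=disc_qaly, life_years=life_years,
        cycle_summary=summary,
    )


def run_all_strategies(
    cohort: Cohort,
    strategies: dict[str, StrategySpec] | list[StrategySpec],
    params: ParameterSet,
    life_table: LifeTable,
    incidence: IncidenceCurve,
    settings: SimulationSettings,
) -> list[StrategyResult]:
    """Run every strategy on the same cohort.

    With common random numbers on (default) the same per-woman disease
    and mortality streams are reused across strategies, so differences
    in outcome are attributable to screening alone.
    """
    specs = list(strategies.values()) if isinstance(strategies, dict) else list(strategies)
    if len(specs) < 1:
        raise ValueError("need at least one strategy")
    return [run_strategy(cohort, s, params, life_table, incidence, settings) for s in specs]


def results_table(results: list[StrategyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results]).set_index("strategy")


def simulate_individual(
    entry_age: int,
    strategy: StrategySpec,
    params: ParameterSet,
    life_table: LifeTable,
    incidence: IncidenceCurve,
    seed: int = 0,
) -> Trajectory:
    """Simulate one woman with a full per-cycle ledger (trace mode)."""
    if not 40 <= entry_age <= 49:
        raise ValueError("entry age must lie in [40, 49]")
    cohort = Cohort(entry_ages=np.array([entry_age]), seed=seed)
    settings = SimulationSettings(n_individuals=1, master_seed=seed, trace=True)
    res = run_strategy(cohort, strategy, params, life_table, incidence, settings)
    frame = res.cycle_summary
    ledger = AccrualLedger()
    for _, row in frame.iterrows():
        ledger.add(int(row["cycle"]), float(row["mean_cost"]), float(np.clip(row["mean_utility"], 0, 1)))
    return Trajectory(
        entry_age=entry_age, frame=frame, ledger=ledger,
        discounted_cost=float(res.costs[0]), discounted_qaly=float(res.qalys[0]),
        life_years=float(res.life_years[0]),
    )


def validate_life_expectancy(
    life_table: LifeTable,
    n: int = 100_000,
    seed: int = 0,
    entry_age: int = 40,
) -> dict:
    """Disease-free validation harness: simulated vs analytic e(entry_age).

    With all disease switched off, simulated mean lifespan must match
    the life table's analytic remaining life expectancy within Monte
    Carlo error; this is the model's mortality-calibration check.
    """
    from .parameters import load_parameters
    from .synthetic import MAX_AGE

    params = load_parameters()
    zero = IncidenceCurve(ages=np.arange(0, MAX_AGE + 1), incidence=np.zeros(MAX_AGE + 1))
    null_strategy = StrategySpec(id="null", label="no screening", schedule=[],
                                 participation_source="fixed", participation=0.0)
    cohort = Cohort(entry_ages=np.full(n, entry_age, dtype=np.int16), seed=seed)
    settings = SimulationSettings(n_individuals=n, master_seed=seed)
    res = run_strategy(cohort, null_strategy, params, life_table, zero, settings)
    analytic = life_table.life_expectancy(entry_age)
    mc_se = float(res.life_years.std(ddof=1) / np.sqrt(n))
    return {
        "analytic": analytic,
        "simulated": float(res.life_years.mean()),
        "mc_se": mc_se,
        "z": (float(res.life_years.mean()) - analytic) / mc_se if mc_se > 0 else 0.0,
        "n": n,
    }
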