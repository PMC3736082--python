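"""Disease-process model: onset, stage at detection, recurrence and death.

Health states follow the usual screening-model compartments: healthy,
DCIS, invasive TNM stages 1-4, advanced (metastatic-equivalent) disease
after a regional/systemic recurrence, and the two absorbing death
states.  All transitions are annual Bernoulli/categorical draws whose
probabilities come from the :class:`~bcscreen.parameters.ParameterSet`:

* clinical onset at the age-specific incidence rate, with stage drawn
  from the clinical-route stage distribution;
* annual recurrence from DCIS/S1/S2/S3, split into local (re-enters the
  treated pathway of the same stage) versus regional/systemic (moves to
  advanced disease);
* annual breast-cancer death with multiplicative modifiers: the
  screened-vs-clinical detection RR, prognostic-subtype RRs in advanced
  disease, and adjuvant-treatment RRs in stages 2-3;
* annual other-cause death from the all-cause life table.

Every function is vectorised over women: scalar inputs work through
length-1 arrays.  Overdiagnosed screen-detected cases accrue diagnosis
and treatment costs and disease utilities but carry zero breast-cancer
death and recurrence hazards — that is what "overdiagnosed" means here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

# compartments
HEALTHY, DCIS, S1, S2, S3, S4, ADVANCED, DEAD_BC, DEAD_OTHER = range(9)
COMPARTMENT_NAMES = (
    "healthy", "DCIS", "S1", "S2", "S3", "S4",
    "advanced_disease", "dead_bc", "dead_other",
)
CANCER_COMPARTMENTS = (DCIS, S1, S2, S3, S4, ADVANCED)
RECURRABLE = (DCIS, S1, S2, S3)
STAGE_KEYS = ("DCIS", "S1", "S2", "S3", "S4")

# detection modes
DETECT_NONE, DETECT_CLINICAL, DETECT_SCREEN = 0, 1, 2

# subtypes
SUB_NONE, SUB_LUMA, SUB_LUMB, SUB_HER2, SUB_TN = 0, 1, 2, 3, 4
SUBTYPE_NAMES = ("none", "LumA", "LumB", "HER2", "TN")
HORMONE_POSITIVE = (SUB_LUMA, SUB_LUMB)

# treatment bitmask
T_SURGERY, T_RADIO, T_CHEMO, T_ENDOCRINE, T_TRASTUZUMAB = 1, 2, 4, 8, 16
TREATMENT_NAMES = {
    T_SURGERY: "surgery", T_RADIO: "radiotherapy", T_CHEMO: "chemo",
    T_ENDOCRINE: "endocrine", T_TRASTUZUMAB: "trastuzumab",
}


def stage_index(compartment):
    """Map compartment codes to stage-table rows (advanced uses stage-4 rows)."""
    c = np.asarray(compartment)
    idx = c - DCIS
    return np.where(c == ADVANCED, S4 - DCIS, idx)


@dataclass(frozen=True)
class HealthState:
    """One woman's health state, used in traces and scalar-level tests."""

    compartment: int = HEALTHY
    years_since_diagnosis: int = 0
    detection_mode: int = DETECT_NONE
    overdiagnosed: bool = False
    subtype: int = SUB_NONE
    treatments: int = 0

    def __post_init__(self):
        if self.compartment == HEALTHY and self.subtype != SUB_NONE:
            raise ValueError("healthy women carry no prognostic subtype")
        if self.compartment in CANCER_COMPARTMENTS and self.subtype == SUB_NONE:
            raise ValueError("diagnosed women must carry a prognostic subtype")
        if self.overdiagnosed and self.detection_mode != DETECT_SCREEN:
            raise ValueError("overdiagnosis is only defined for screen-detected cases")
        if self.years_since_diagnosis < 0:
            raise ValueError("years_since_diagnosis must be >= 0")

    @property
    def alive(self) -> bool:
        return self.compartment not in (DEAD_BC, DEAD_OTHER)

    @property
    def treatment_names(self) -> frozenset:
        return frozenset(n for b, n in TREATMENT_NAMES.items() if self.treatments & b)


# ---------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------


def dcis_ramp_multiplier(years_since_program_start: int, ramp_years: int = 10,
                         plateau: float = 2.0) -> float:
    """DCIS-detection multiplier: rises from 1 at programme start to its
    plateau after ``ramp_years`` (screening inflates in-situ detection
    until rates stabilise), constant thereafter."""
    if years_since_program_start < 0:
        raise ValueError("years since programme start must be >= 0")
    if ramp_years < 1:
        raise ValueError("ramp_years must be >= 1")
    frac = min(years_since_program_start, ramp_years) / ramp_years
    return 1.0 + (plateau - 1.0) * frac


def clinical_stage_probs(params: ParameterSet) -> np.ndarray:
    """Normalised (DCIS, S1, S2, S3, S4) fractions for clinically surfacing cancer."""
    return params.stage_clinical.probabilities()


def clinical_onset(age, incidence, params: ParameterSet, rng: np.random.Generator):
    """Annual clinical-onset draw for healthy women.

    Returns (onset_mask, stage_codes): stage codes are compartment
    constants (DCIS..S4), valid where onset occurred.
    """
    age = np.atleast_1d(age)
    p = incidence.rate_at(age)
    onset = rng.random(age.shape) < p
    probs = clinical_stage_probs(params)
    stages = draw_stage(probs, rng.random(age.shape))
    return onset, stages


def draw_stage(probs: np.ndarray, u) -> np.ndarray:
    """Inverse-CDF categorical draw over (DCIS..S4) given uniforms."""
    cum = np.cumsum(probs)
    return DCIS + np.searchsorted(cum, np.atleast_1d(u), side="right").clip(0, 4)


def assign_subtype(prevalence: dict[str, float], rng: np.random.Generator, size=None):
    """Categorical prognostic-subtype draw (LumA/LumB/HER2/TN)."""
    total = sum(prevalence.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"subtype prevalence sums to {total}, not 1")
    order = ("LumA", "LumB", "HER2", "TN")
    p = np.array([prevalence[k] for k in order])
    cum = np.cumsum(p)
    u = rng.random() if size is None else rng.random(size)
    codes = SUB_LUMA + np.searchsorted(cum, np.atleast_1d(u), side="right").clip(0, 3)
    return int(codes[0]) if size is None else codes


def assign_treatments(stage, subtype) -> np.ndarray:
    """Deterministic default treatment mix by stage and subtype.

    DCIS: surgery + radiotherapy, no systemic therapy.  Invasive:
    surgery + radiotherapy; chemotherapy for stage >= 2 and for
    HER2/triple-negative stage 1; endocrine therapy for hormone-positive
    disease; trastuzumab only in stages 2-3 for HER2-positive women
    (adjuvant, one year).  Stage 4 at diagnosis: palliative chemo and
    endocrine therapy where hormone-positive.
    """
    stage = np.atleast_1d(np.asarray(stage))
    subtype = np.atleast_1d(np.asarray(subtype))
    t = np.full(stage.shape, T_SURGERY | T_RADIO, dtype=np.uint8)
    hr_pos = np.isin(subtype, HORMONE_POSITIVE)
    invasive = stage >= S1
    t = np.where(invasive & hr_pos, t | T_ENDOCRINE, t)
    chemo = (stage >= S2) | (invasive & np.isin(subtype, (SUB_HER2, SUB_TN)))
    t = np.where(chemo, t | T_CHEMO, t)
    trast = np.isin(stage, (S2, S3)) & (subtype == SUB_HER2)
    t = np.where(trast, t | T_TRASTUZUMAB, t)
    # stage 4 / advanced: palliative systemic therapy only (no radio bit removed
    # for simplicity of the cost aggregate; utilities use the advanced weight)
    return t.astype(np.uint8)


def _treatment_rr(treatments, params: ParameterSet) -> np.ndarray:
    treatments = np.atleast_1d(np.asarray(treatments))
    rr = np.ones(treatments.shape)
    tr = params.treatment
    rr = np.where(treatments & T_CHEMO, rr * tr.rr_taxane.point_estimate, rr)
    rr = np.where(treatments & T_ENDOCRINE, rr * tr.rr_aromatase.point_estimate, rr)
    rr = np.where(treatments & T_TRASTUZUMAB, rr * tr.rr_trastuzumab.point_estimate, rr)
    return rr


def recurrence_hazard(compartment, treatments, overdiagnosed, params: ParameterSet) -> np.ndarray:
    """Annual recurrence probability: stage base rate x adjuvant-treatment RRs."""
    compartment = np.atleast_1d(np.asarray(compartment))
    base = np.zeros(compartment.shape)
    for comp in RECURRABLE:
        key = STAGE_KEYS[comp - DCIS]
        base = np.where(compartment == comp,
                        params.nat_hist.recurrence_annual[key].point_estimate, base)
    p = base * _treatment_rr(treatments, params)
    p = np.where(np.atleast_1d(overdiagnosed), 0.0, p)
    return np.clip(p, 0.0, 1.0)


def annual_recurrence(compartment, treatments, overdiagnosed, params: ParameterSet,
                      rng: np.random.Generator):
    """Draw recurrence events; returns (recurs, local) boolean masks.

    ``local`` recurrences re-enter the same stage's treated pathway;
    non-local (regional/systemic) recurrences move to advanced disease.
    """
    compartment = np.atleast_1d(np.asarray(compartment))
    p = recurrence_hazard(compartment, treatments, overdiagnosed, params)
    recurs = rng.random(compartment.shape) < p
    local_frac = np.zeros(compartment.shape)
    for comp in RECURRABLE:
        key = STAGE_KEYS[comp - DCIS]
        local_frac = np.where(
            compartment == comp,
            params.nat_hist.recurrence_local_fraction[key].point_estimate, local_frac)
    local = recurs & (rng.random(compartment.shape) < local_frac)
    return recurs, local


def bc_death_hazard(compartment, detection_mode, subtype, treatments, overdiagnosed,
                    params: ParameterSet) -> np.ndarray:
    """Annual breast-cancer death probability with multiplicative modifiers.

    base(stage) x 0.62-type RR if screen-detected x subtype RR in
    advanced disease x adjuvant-treatment RRs in stages 2-3; zero for
    overdiagnosed cases.
    """
    compartment = np.atleast_1d(np.asarray(compartment))
    detection_mode = np.atleast_1d(np.asarray(detection_mode))
    subtype = np.atleast_1d(np.asarray(subtype))
    treatments = np.atleast_1d(np.asarray(treatments))
    nh = params.nat_hist
    base = np.zeros(compartment.shape)
    for comp in (DCIS, S1, S2, S3, S4):
        base = np.where(compartment == comp,
                        nh.bc_death_annual[STAGE_KEYS[comp - DCIS]].point_estimate, base)
    base = np.where(compartment == ADVANCED, nh.bc_death_annual["S4"].point_estimate, base)
    p = base
    p = np.where(detection_mode == DETECT_SCREEN, p * nh.screened_rr_death.point_estimate, p)
    sub_rr = np.ones(compartment.shape)
    for code, key in ((SUB_LUMB, "LumB"), (SUB_HER2, "HER2"), (SUB_TN, "TN")):
        sub_rr = np.where(subtype == code, nh.subtype_rr_advanced[key].point_estimate, sub_rr)
    p = np.where(compartment == ADVANCED, p * sub_rr, p)
    in_s23 = np.isin(compartment, (S2, S3))
    p = np.where(in_s23, p * _treatment_rr(treatments, params), p)
    p = np.where(np.atleast_1d(overdiagnosed), 0.0, p)
    return np.clip(p, 0.0, 1.0)


def annual_bc_death(compartment, detection_mode, subtype, treatments, overdiagnosed,
                    params: ParameterSet, rng: np.random.Generator) -> np.ndarray:
    p = bc_death_hazard(compartment, detection_mode, subtype, treatments,
                        overdiagnosed, params)
    return rng.random(p.shape) < p


def annual_other_death(age, life_table, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(q(age)) draw from the all-cause life table."""
    age = np.atleast_1d(np.asarray(age))
    q = life_table.q_at(age)
    return rng.random(age.shape) < q
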