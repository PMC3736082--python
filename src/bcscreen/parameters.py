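"""Model parameters: point estimates, ranges and sampling distributions.

Every quantity that drives the simulation — test performance, stage
distributions at detection, transition probabilities, relative risks,
unit costs, utility weights and economic settings — is represented as a
:class:`DistributionSpec`: a point estimate used in the base case, an
optional plausible range, and a sampling distribution used in
probabilistic sensitivity analysis (PSA).

The packaged default parameter file (``data/default_parameters.json``)
holds the full input vector for the Brazilian mammography-screening
evaluation: SF-6D utility weights, 2010 R$ unit costs from public-payer
reimbursement data, BCSC-derived mammography sensitivities, and
stage-specific annual recurrence/death probabilities.  Users override
any subset of it with a deep-merged JSON/dict config.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from importlib import resources
from typing import Any, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

logger = logging.getLogger(__name__)

Family = Literal["point", "uniform", "beta", "gamma", "lognormal", "normal"]

STAGES = ("DCIS", "S1", "S2", "S3", "S4")
INVASIVE_STAGES = ("S1", "S2", "S3", "S4")
SUBTYPES = ("LumA", "LumB", "HER2", "TN")
MODALITIES = ("SFM", "FFDM")
AGE_BANDS = ("40-49", "50-59", "60-69")
ROUNDS = ("prevalence", "incidence")


class DistributionSpec(BaseModel):
    """One model input: base-case point estimate plus PSA distribution.

    ``low``/``high`` double as the printed plausible range (used for
    one-way sensitivity analysis) and, for ``family="uniform"``, as the
    distribution's support.  Gamma is parameterised by shape ``alpha``
    and rate ``rate``; lognormal by ``mu``/``sigma`` on the log scale.
    Probabilities are clamped to [0, 1] on sampling.
    """

    model_config = ConfigDict(frozen=True)

    family: Family = "point"
    point_estimate: float
    low: Optional[float] = None
    high: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    rate: Optional[float] = None
    sd: Optional[float] = None
    probability: bool = False
    note: Optional[str] = None

    @model_validator(mode="after")
    def _check_family(self) -> "DistributionSpec":
        f = self.family
        if f == "uniform":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError("uniform requires low < high")
        elif f == "beta":
            if not (self.alpha and self.alpha > 0 and self.beta and self.beta > 0):
                raise ValueError("beta requires alpha > 0 and beta > 0")
        elif f == "gamma":
            if not (self.alpha and self.alpha > 0 and self.rate and self.rate > 0):
                raise ValueError("gamma requires shape alpha > 0 and rate > 0")
        elif f == "lognormal":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValueError("lognormal requires mu and sigma > 0")
        elif f == "normal":
            if self.mu is None or self.sd is None or self.sd <= 0:
                raise ValueError("normal requires mu (mean) and sd > 0")
        if self.low is not None and self.high is not None:
            if not (self.low - 1e-12 <= self.point_estimate <= self.high + 1e-12):
                raise ValueError(
                    f"point estimate {self.point_estimate} outside range "
                    f"[{self.low}, {self.high}]"
                )
        if self.probability and not 0.0 <= self.point_estimate <= 1.0:
            raise ValueError(f"probability point estimate {self.point_estimate} outside [0, 1]")
        return self

    # -- closed forms -------------------------------------------------

    def _frozen(self):
        if self.family == "uniform":
            return stats.uniform(self.low, self.high - self.low)
        if self.family == "beta":
            return stats.beta(self.alpha, self.beta)
        if self.family == "gamma":
            return stats.gamma(self.alpha, scale=1.0 / self.rate)
        if self.family == "lognormal":
            return stats.lognorm(self.sigma, scale=math.exp(self.mu))
        if self.family == "normal":
            return stats.norm(self.mu, self.sd)
        raise ValueError(f"no distribution for family {self.family!r}")

    def mean(self) -> float:
        """Closed-form mean; the point estimate for family='point'."""
        if self.family == "point":
            return self.point_estimate
        if self.family == "uniform":
            return 0.5 * (self.low + self.high)
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta)
        if self.family == "gamma":
            return self.alpha / self.rate
        if self.family == "lognormal":
            return math.exp(self.mu + 0.5 * self.sigma**2)
        return self.mu  # normal

    def median(self) -> float:
        if self.family == "point":
            return self.point_estimate
        if self.family == "lognormal":
            return math.exp(self.mu)
        if self.family == "normal":
            return self.mu
        if self.family == "uniform":
            return 0.5 * (self.low + self.high)
        return float(self._frozen().ppf(0.5))  # beta/gamma: numeric

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must be in (0, 1), got {q}")
        if self.family == "point":
            return self.point_estimate
        return float(self._frozen().ppf(q))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the PSA distribution; probabilities clamped to [0, 1]."""
        if self.family == "point":
            return self.point_estimate if size is None else np.full(size, self.point_estimate)
        x = self._frozen().rvs(size=size, random_state=rng)
        if self.probability:
            clipped = np.clip(x, 0.0, 1.0)
            n_trunc = int(np.sum(clipped != x)) if size is not None else int(clipped != x)
            if n_trunc:
                logger.info("clamped %d draw(s) to [0, 1]", n_trunc)
            x = clipped
        return float(x) if size is None else x

    def collapsed(self, value: float | None = None) -> "DistributionSpec":
        """A point-mass copy at ``value`` (default: the point estimate)."""
        v = self.point_estimate if value is None else float(value)
        if self.probability:
            v = min(max(v, 0.0), 1.0)
        return DistributionSpec(family="point", point_estimate=v, probability=self.probability, note=self.note)


def distribution_mean(d: DistributionSpec) -> float:
    return d.mean()


def distribution_median(d: DistributionSpec) -> float:
    return d.median()


def distribution_quantile(d: DistributionSpec, q: float) -> float:
    return d.quantile(q)


# ---------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------


class TestPerformance(BaseModel):
    """Mammography sensitivity by modality and age band, and recall cascade rates."""

    sensitivity: dict[str, dict[str, DistributionSpec]]
    recall_rate: dict[str, dict[str, DistributionSpec]]
    fna_fraction: DistributionSpec
    biopsy_fraction: DistributionSpec

    @model_validator(mode="after")
    def _check(self) -> "TestPerformance":
        for mod in MODALITIES:
            bands = self.sensitivity.get(mod, {})
            if set(bands) != set(AGE_BANDS):
                raise ValueError(f"sensitivity[{mod}] must cover age bands {AGE_BANDS}")
            for band, spec in bands.items():
                if not 0.0 <= spec.point_estimate <= 1.0:
                    raise ValueError(f"sensitivity[{mod}][{band}] outside [0, 1]")
            rr = self.recall_rate.get(mod, {})
            if set(rr) != set(ROUNDS):
                raise ValueError(f"recall_rate[{mod}] must cover rounds {ROUNDS}")
            if rr["prevalence"].point_estimate < rr["incidence"].point_estimate:
                raise ValueError(f"recall_rate[{mod}]: prevalence round must be >= incidence round")
        for frac in (self.fna_fraction, self.biopsy_fraction):
            if not 0.0 <= frac.point_estimate <= 1.0:
                raise ValueError("workup fractions must be probabilities")
        return self

    def sensitivity_value(self, modality: str, age: int) -> float:
        if age < 50:
            band = "40-49"
        elif age < 60:
            band = "50-59"
        else:
            band = "60-69"
        return self.sensitivity[modality][band].point_estimate


class StageDistribution(BaseModel):
    """Stage at detection for one diagnostic route.

    For the clinical route the five fractions are unconditional.  For
    the screen route the invasive fractions are conditional on invasive
    disease; the DCIS component is handled separately (it ramps with
    programme time).
    """

    route: Literal["clinical", "screen"]
    dcis: DistributionSpec
    s1: DistributionSpec
    s2: DistributionSpec
    s3: DistributionSpec
    s4: DistributionSpec

    def _raw(self) -> np.ndarray:
        return np.array(
            [s.point_estimate for s in (self.dcis, self.s1, self.s2, self.s3, self.s4)]
        )

    def probabilities(self) -> np.ndarray:
        """Normalised 5-vector over (DCIS, S1, S2, S3, S4); clinical route only."""
        p = self._raw()
        total = p.sum()
        if total <= 0 or np.any(p < 0):
            raise ValueError(f"{self.route} stage distribution not normalisable: {p}")
        p = p / total
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stage distribution fails to sum to 1 after normalization")
        return p

    def invasive_conditional(self) -> np.ndarray:
        """Normalised 4-vector over invasive stages (S1..S4)."""
        p = self._raw()[1:]
        total = p.sum()
        if total <= 0 or np.any(p < 0):
            raise ValueError("invasive stage fractions not normalisable")
        return p / total

    @model_validator(mode="after")
    def _check(self) -> "StageDistribution":
        self.probabilities() if self.route == "clinical" else self.invasive_conditional()
        return self


class NaturalHistoryParams(BaseModel):
    """Disease-process probabilities: recurrence, BC death, overdiagnosis, prognosis."""

    recurrence_annual: dict[str, DistributionSpec]
    recurrence_local_fraction: dict[str, DistributionSpec]
    bc_death_annual: dict[str, DistributionSpec]
    overdiagnosis: DistributionSpec
    dcis_ramp_years: int = 10
    dcis_plateau_multiplier: float = 2.0
    screened_rr_death: DistributionSpec
    subtype_rr_advanced: dict[str, DistributionSpec]
    subtype_prevalence: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "NaturalHistoryParams":
        for name, table, keys in (
            ("recurrence_annual", self.recurrence_annual, ("DCIS", "S1", "S2", "S3")),
            ("recurrence_local_fraction", self.recurrence_local_fraction, ("DCIS", "S1", "S2", "S3")),
            ("bc_death_annual", self.bc_death_annual, STAGES),
        ):
            missing = set(keys) - set(table)
            if missing:
                raise ValueError(f"{name} missing stages {sorted(missing)}")
            for k in keys:
                if not 0.0 <= table[k].point_estimate <= 1.0:
                    raise ValueError(f"{name}[{k}] outside [0, 1]")
        if not 0.0 <= self.overdiagnosis.point_estimate <= 0.30 + 1e-12:
            raise ValueError("overdiagnosis probability outside plausible range [0, 0.30]")
        if set(self.subtype_prevalence) != set(SUBTYPES):
            raise ValueError(f"subtype_prevalence must cover {SUBTYPES}")
        total = sum(self.subtype_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_prevalence sums to {total}, not 1")
        if self.dcis_ramp_years < 1:
            raise ValueError("dcis_ramp_years must be >= 1")
        if self.dcis_plateau_multiplier < 1.0:
            raise ValueError("dcis_plateau_multiplier must be >= 1")
        missing = {"LumB", "HER2", "TN"} - set(self.subtype_rr_advanced)
        if missing:
            raise ValueError(f"subtype_rr_advanced missing {sorted(missing)}")
        return self


class TreatmentEffects(BaseModel):
    """Relative risks of adjuvant therapy and treatment-complication rates."""

    rr_taxane: DistributionSpec
    rr_aromatase: DistributionSpec
    rr_trastuzumab: DistributionSpec
    complication_annual: dict[str, DistributionSpec]
    downstage_or_ffdm_under50: DistributionSpec
    complication_cost: float = 509.0
    complication_disutility: float = 0.02
    endocrine_years: int = 5

    @model_validator(mode="after")
    def _check(self) -> "TreatmentEffects":
        for name, spec in (
            ("rr_taxane", self.rr_taxane),
            ("rr_aromatase", self.rr_aromatase),
            ("rr_trastuzumab", self.rr_trastuzumab),
            ("downstage_or_ffdm_under50", self.downstage_or_ffdm_under50),
        ):
            if spec.point_estimate <= 0:
                raise ValueError(f"{name} point estimate must be > 0")
        for k in ("chemo", "endocrine"):
            if k not in self.complication_annual:
                raise ValueError(f"complication_annual missing {k!r}")
            if not 0.0 <= self.complication_annual[k].point_estimate <= 1.0:
                raise ValueError(f"complication_annual[{k}] outside [0, 1]")
        return self


class CostTable(BaseModel):
    """Unit costs in 2010 Brazilian reais (R$)."""

    medical_visit: DistributionSpec
    sfm: DistributionSpec
    ffdm: DistributionSpec
    biopsy: DistributionSpec
    recall_sfm: DistributionSpec
    recall_ffdm: DistributionSpec
    staging_early: DistributionSpec
    staging_advanced: DistributionSpec
    first_year: dict[str, DistributionSpec]
    subsequent_year: dict[str, DistributionSpec]

    @model_validator(mode="after")
    def _check(self) -> "CostTable":
        for name in ("medical_visit", "sfm", "ffdm", "biopsy", "recall_sfm",
                     "recall_ffdm", "staging_early", "staging_advanced"):
            if getattr(self, name).point_estimate < 0:
                raise ValueError(f"cost {name} must be >= 0")
        for table in (self.first_year, self.subsequent_year):
            missing = set(STAGES) - set(table)
            if missing:
                raise ValueError(f"stage cost table missing {sorted(missing)}")
            for k, v in table.items():
                if v.point_estimate < 0:
                    raise ValueError(f"stage cost {k} must be >= 0")
        for st in ("S1", "S2", "S3"):
            if self.first_year[st].point_estimate < self.subsequent_year[st].point_estimate:
                raise ValueError(f"first-year cost for {st} below subsequent-year cost")
        return self

    def modality_cost(self, modality: str) -> float:
        return (self.sfm if modality == "SFM" else self.ffdm).point_estimate

    def recall_cost(self, modality: str) -> float:
        return (self.recall_sfm if modality == "SFM" else self.recall_ffdm).point_estimate


class UtilityTable(BaseModel):
    """SF-6D utility weights by health state."""

    healthy: DistributionSpec
    healthy_false_positive: DistributionSpec
    followup_nonmetastatic: DistributionSpec
    early_endocrine: DistributionSpec
    early_chemo: DistributionSpec
    s3_endocrine: DistributionSpec
    s3_chemo: DistributionSpec
    s4: DistributionSpec

    @model_validator(mode="after")
    def _check(self) -> "UtilityTable":
        h = self.healthy.point_estimate
        for name in ("healthy", "healthy_false_positive", "followup_nonmetastatic",
                     "early_endocrine", "early_chemo", "s3_endocrine", "s3_chemo", "s4"):
            u = getattr(self, name).point_estimate
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {name}={u} outside [0, 1]")
            if u > h + 1e-12:
                raise ValueError(f"utility {name}={u} exceeds healthy utility {h}")
        return self


class EconomicSettings(BaseModel):
    discount_rate: DistributionSpec
    currency: str = "BRL 2010"
    wtp_thresholds: list[float] = Field(default_factory=lambda: [17869.0, 53607.0])
    half_cycle_correction: bool = True

    @model_validator(mode="after")
    def _check(self) -> "EconomicSettings":
        r = self.discount_rate.point_estimate
        if not 0.0 <= r <= 0.10 + 1e-12:
            raise ValueError(f"discount rate {r} outside [0, 0.10]")
        return self


class Coverage(BaseModel):
    """Annual screening participation: opportunistic (usual care) and organised."""

    opportunistic: DistributionSpec
    organized: DistributionSpec

    @model_validator(mode="after")
    def _check(self) -> "Coverage":
        for name in ("opportunistic", "organized"):
            if not 0.0 <= getattr(self, name).point_estimate <= 1.0:
                raise ValueError(f"coverage {name} outside [0, 1]")
        return self


class ParameterSet(BaseModel):
    """The complete model input vector."""

    test_performance: TestPerformance
    stage_clinical: StageDistribution
    stage_screen: StageDistribution
    nat_hist: NaturalHistoryParams
    treatment: TreatmentEffects
    costs: CostTable
    utilities: UtilityTable
    econ: EconomicSettings
    coverage: Coverage
    base_case_flag: bool = False

    @model_validator(mode="after")
    def _routes(self) -> "ParameterSet":
        if self.stage_clinical.route != "clinical" or self.stage_screen.route != "screen":
            raise ValueError("stage distributions must carry their own route labels")
        return self


# ---------------------------------------------------------------------
# loading, base case, PSA
# ---------------------------------------------------------------------


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def packaged_defaults() -> dict:
    """The packaged default parameter dictionary (deep copy)."""
    text = resources.files("bcscreen").joinpath("data/default_parameters.json").read_text()
    return json.loads(text)


def load_parameters(config: dict | str | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from packaged defaults plus overrides.

    ``config`` may be ``None`` (pure defaults), a dict of overrides, or a
    path to a JSON file of overrides; overrides are merged by deep update.
    """
    raw = packaged_defaults()
    if config is not None:
        if isinstance(config, str):
            with open(config) as fh:
                config = json.load(fh)
        if not isinstance(config, dict):
            raise TypeError("config must be a dict or a path to a JSON file")
        raw = _deep_update(raw, config)
    return ParameterSet.model_validate(raw)


def _walk_specs(node: Any, path: str = ""):
    """Yield (dotted_path, spec_dict) for every DistributionSpec-like dict."""
    if isinstance(node, dict):
        if "family" in node and "point_estimate" in node:
            yield path, node
        else:
            for k, v in node.items():
                yield from _walk_specs(v, f"{path}.{k}" if path else str(k))


def base_case(ps: ParameterSet) -> ParameterSet:
    """Collapse every sampling distribution to its point estimate (idempotent)."""
    raw = ps.model_dump()
    for _, spec in _walk_specs(raw):
        spec.update(
            family="point",
            low=None, high=None, alpha=None, beta=None,
            mu=None, sigma=None, rate=None, sd=None,
        )
    raw["base_case_flag"] = True
    return ParameterSet.model_validate(raw)


def sample_psa_draw(ps: ParameterSet, seed: int) -> ParameterSet:
    """One joint PSA draw: every distributed parameter replaced by a sample.

    Each parameter has its own counter-based stream keyed by the master
    seed and the parameter's dotted path, so adding or removing one
    parameter leaves all other draws unchanged.  Probability draws are
    clamped to [0, 1]; the same seed reproduces the draw bit-for-bit.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    raw = ps.model_dump()
    for path, spec_dict in _walk_specs(raw):
        spec = DistributionSpec.model_validate(spec_dict)
        if spec.family == "point":
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(path.encode()),))
        )
        try:
            value = spec.sample(rng)
        except ValueError as exc:
            raise ValueError(f"invalid distribution for parameter {path!r}: {exc}") from exc
        spec_dict.update(
            family="point", point_estimate=float(value),
            low=None, high=None, alpha=None, beta=None,
            mu=None, sigma=None, rate=None, sd=None,
        )
    # disease-state utilities are capped at the healthy utility so a draw
    # cannot invert the health-state ordering
    healthy = raw["utilities"]["healthy"]["point_estimate"]
    for key, spec_dict in raw["utilities"].items():
        if key != "healthy" and spec_dict["point_estimate"] > healthy:
            spec_dict["point_estimate"] = healthy
    raw["base_case_flag"] = False
    return ParameterSet.model_validate(raw)


# ---------------------------------------------------------------------
# consistency report
# ---------------------------------------------------------------------


def consistency_report(ps: ParameterSet | None = None) -> list[dict]:
    """Cross-check printed point estimates against their distribution's closed form.

    For every parameter whose PSA distribution implies a closed-form
    central value (beta/gamma → mean, lognormal → median), compare that
    value with the packaged point estimate at the precision the point
    estimate is quoted to.  Known discrepancies in the source tables
    (gamma-cost shape/rate pairs, the stage-1 clinical beta, the FFDM
    downstage odds ratio, the Luminal-B relative risk, the stage-4
    clinical complement and the stage-3 recurrence range) are reported
    here rather than silently repaired: the printed point estimates stay
    in force for the base case.
    """
    ps = ps or load_parameters()
    raw = ps.model_dump()
    rows: list[dict] = []
    for path, spec_dict in _walk_specs(raw):
        spec = DistributionSpec.model_validate(spec_dict)
        if spec.family in ("point", "uniform", "normal"):
            continue
        central = spec.median() if spec.family == "lognormal" else spec.mean()
        pe = spec.point_estimate
        # printed precision: infer decimals from the point estimate's magnitude
        decimals = 2 if abs(pe) < 10 else 0
        if abs(pe) < 0.2:
            decimals = 3
        consistent = round(central, decimals) == round(pe, decimals)
        rows.append(
            {
                "parameter": path,
                "family": spec.family,
                "point_estimate": pe,
                "closed_form": central,
                "statistic": "median" if spec.family == "lognormal" else "mean",
                "consistent": consistent,
            }
        )
    # structural notes that are not single-spec closed forms
    clin = ps.stage_clinical
    others = clin.dcis.point_estimate + clin.s1.point_estimate + clin.s2.point_estimate + clin.s3.point_estimate
    rows.append(
        {
            "parameter": "stage_clinical.s4",
            "family": "complement",
            "point_estimate": clin.s4.point_estimate,
            "closed_form": 1.0 - others,
            "statistic": "1 - sum(other stages)",
            "consistent": abs(clin.s4.point_estimate - (1.0 - others)) < 5e-4,
        }
    )
    s3r = ps.nat_hist.recurrence_annual["S3"]
    if s3r.low is not None and s3r.high is not None:
        rows.append(
            {
                "parameter": "nat_hist.recurrence_annual.S3",
                "family": s3r.family,
                "point_estimate": s3r.point_estimate,
                "closed_form": s3r.high,
                "statistic": "point vs published range max 0.28 (range widened to include the point)",
                "consistent": s3r.point_estimate <= 0.28,
            }
        )
    return rows
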