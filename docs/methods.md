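# Methods

## Model structure and assumptions

The model is an individual-level (micro-simulation) Markov state-transition
model with 1-year cycles, a lifetime horizon (closure at age 110) and
half-cycle correction.  Each woman is simulated from her entry age (40–49)
through the compartments healthy → cancer at detected stage (DCIS, S1–S4) →
local recurrence (returns to the same stage's treated pathway) or
regional/systemic recurrence (moves to an advanced, stage-4-equivalent
compartment) → death from breast cancer or from other causes.  Death states
are absorbing and accrue nothing.

Within a cycle events resolve in a fixed order: other-cause death →
breast-cancer death → recurrence → screening → onset/detection →
complications → accrual.  The fixed order makes runs bit-reproducible; it
also means a woman who dies in a cycle takes part in none of that cycle's
later events and accrues half a cycle of her pre-death state's cost and
utility (the individual-level analogue of the cohort half-cycle rule:
all accruals are discounted at mid-cycle time t + ½).

There is no explicit preclinical sojourn-time state.  Screen detection is
applied to incident disease: a woman whose cancer surfaces in a cycle in
which she attends a screen is screen-detected with the modality- and
age-band-specific sensitivity and draws her stage from the screen-route
distribution; otherwise she is diagnosed clinically with the clinical-route
stages.  A screen-missed (false-negative) case surfaces clinically in the
same cycle.  This is the simplest reading consistent with detection-route
stage distributions given as inputs rather than dwell-time parameters; it
understates the lead-time structure of real programmes, so absolute
stage-shift and mortality effects should be read as stylised.

Overdiagnosis (5 % of screen-detected cases, range 0–30 %) is operationalised
as non-lethal detected disease: flagged cases accrue diagnosis and treatment
costs and disease-state utilities but carry zero breast-cancer death and
recurrence hazards.

## Hazards and modifiers

Annual stage-specific base probabilities: recurrence DCIS 0.008, S1 0.030,
S2 0.087, S3 0.283; breast-cancer death DCIS 0.002, S1 0.009, S2 0.031,
S3 0.090, S4/advanced 0.270.  Modifiers are multiplicative on the annual
probability (clipped to [0, 1]):

- screen-detected cases: death RR 0.62 versus clinical detection;
- advanced disease: prognostic-subtype death RRs versus Luminal A
  (Luminal B 1.42, HER2 1.90, triple-negative 1.62); subtype prevalence
  defaults to LumA 0.55 / LumB 0.15 / HER2 0.15 / TN 0.15 (configurable;
  the source tables print the RRs but no prevalence);
- adjuvant treatment in stages 2–3: taxane chemotherapy 0.86, aromatase
  inhibitor 0.82 (hormone-positive), trastuzumab 0.61 (HER2-positive,
  1 year).  The same treatment RRs are applied to the recurrence hazard of
  treated early-stage disease.

Treatment assignment is deterministic by stage and subtype: DCIS gets surgery
plus radiotherapy and no systemic therapy; invasive disease gets surgery and
radiotherapy, chemotherapy for stage ≥ 2 (and for HER2/TN stage 1), endocrine
therapy for hormone-positive disease (5 years), trastuzumab only for
HER2-positive stages 2–3.  Treatment complications (chemo 16 %/year in the
chemotherapy year, endocrine 5 %/year while on endocrine therapy) trigger a
one-cycle extra cost (default R$ 509) and a one-cycle utility decrement
(default 0.02); the probabilities are inputs, the consequences are package
defaults because no consequence values are printed with them.

## Screening

Strategies A–G as in the README.  Usual care (A) is opportunistic annual SFM
for ages 40–69 at 18 % participation (10–30 %); organised strategies use 70 %
(55–85 %).  Attendance is drawn independently each year.  A biennial schedule
is "due" when at least the interval has elapsed since the woman's last
attended screen.  A woman's first attended screen is her prevalence round
(recall rates 4.29 % FFDM / 3.41 % SFM) and later screens are incidence
rounds (1.69 % / 1.01 %); recalled women undergo repeat imaging, 5 % FNA and
3 % surgical biopsy.  Each recall accrues exactly one recall cost of its
modality.

Stage at screen detection: the DCIS share starts at 6.1 % and rises linearly
to a plateau multiplier (default 2.0) over the programme's first 10 years —
the plateau level is a package choice, as the "dynamic range" of in-situ
inflation is described but not quantified in the source material.  Invasive
stages split 58/32.4/8.3/1.3 % conditional on invasive.  For FFDM under age
50 the early (DCIS+S1+S2) versus late (S3+S4) odds are shifted by the
diagnostic downstage odds ratio (odds_early′ = odds_early / 0.54),
renormalising within each group; the early/late cut is configurable since the
source odds ratio does not define it.

## Parameters, base case and PSA

Every input is a `DistributionSpec`: a base-case point estimate, an optional
plausible range, and a sampling distribution for PSA (beta for fractions,
gamma for skewed costs, lognormal for relative risks, normal for utilities,
uniform where only a min–max range is given).  Printed point estimates are
never overridden: where a distribution's closed form disagrees with the
printed value (the gamma cost rows, the stage-1 clinical beta, the downstage
odds ratio, the Luminal-B RR, the stage-4 clinical "complement", the stage-3
recurrence range), the discrepancy is flagged by
`bcscreen.consistency_report()` and the distribution is used only for PSA
spread.  The clinical stage-4 fraction defaults to the complement of the
other printed fractions (0.066) so the distribution sums to 1.

PSA draws use one counter-based stream per parameter, keyed by (master seed,
dotted parameter path), so adding a parameter does not perturb other draws.
Probability draws are clamped to [0, 1] and sampled disease-state utilities
are capped at the healthy utility to preserve the health-state ordering.
The discount rate (5 %, range 0–10 %) is varied in one-way sensitivity
analysis but not sampled in PSA — its range expresses guideline bounds, not
sampling uncertainty.

## Synthetic calibration inputs

The generators replace registry inputs with the structure the analysis
assumes:

- **Life table**: Gompertz adult mortality h(x) = a·e^{bx} with slope
  b = 0.10/year, scaled so the analytic remaining life expectancy at 40
  equals a target level (default 40.0 years, within ±0.1), closed at age 110.
- **Incidence**: a logistic age-increasing onset curve, zero below age 30,
  scaled so the mean annual onset probability over ages 40–69 equals
  50/100,000 (±1 %); regional scenarios scale it exactly linearly
  (multipliers 0.5–1.5) and override opportunistic coverage within 10–30 %.
- **Cohort**: multinomial entry-age draws over 40–49; the base case enters
  everyone at 40.

What the generators do *not* emulate: cohort and period trends in incidence,
the real age profile of Brazilian all-cause mortality below 40, regional
life-table differences, and the absolute level of registry incidence at old
ages.  Consequently the simulated absolute costs and QALYs are not
comparable number-for-number with results calibrated to registry curves;
passing tests demonstrate internal correctness (parameter recovery,
calibration of the mortality model, dominance logic, variance reduction) and
qualitative behaviour (screening buys QALYs at extra cost, earlier stage at
diagnosis), not external validity.

## Numerical choices

- RNG: one stream per (purpose, cycle) keyed by the master seed; woman *i*
  always consumes element *i*, giving common random numbers across
  strategies by construction and insensitivity to strategy-dependent draw
  counts.  Turning CRN off adds a strategy key to the streams.
- Stage distributions are renormalised (tolerance 1e-9) after PSA draws of
  their components.
- Frontier ties: strategies sort by (cost, −QALY, id); an exact duplicate
  (cost, QALY) pair is flagged as simply dominated in favour of the
  earlier-sorting strategy.  Exact NMB ties in the CEAC split probability
  equally.  Frontier ICERs are asserted strictly increasing on every call.
- ICERs are kept unrounded internally; display rounding is R$ 1.
- One-way SA and PSA rerun the engine with CRN; PSA uses a reduced inner
  cohort (default 2,000 women per draw) as a compute/precision trade-off —
  the inner size is a configuration knob and CEAC stability should be
  checked against it.
- Problem sizes in the test-suite checks: stage-recovery and life-expectancy
  calibration at n = 100,000 women; hazard-ratio recovery at 10⁶
  person-years; CRN variance comparison at n = 10,000; frontier oracle
  equivalence on 1,000 random instances.

## Known limitations

- No explicit sojourn time or interval-cancer mechanism; a screen-missed
  cancer cannot be caught at a later round before surfacing clinically.
- Stage- and state-specific survival is time-constant within a state; the
  source describes "time-dependent" relative survival without giving the
  functional form.
- DCIS treatment costs are not separately priced in the inputs and default
  to the stage-1 aggregate rows (configurable).
- The advanced-disease utility (0.680) applies throughout advanced disease;
  no separate first-year value is printed.
- Cancer survivors remain in follow-up states for life (no cure transition),
  so long-horizon subsequent-year costs are an upper bound.
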