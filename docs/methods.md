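# Methods

This note documents the model, its assumptions, the synthetic-data
generator, and the numerical choices made where the design was open.

## Simulation engine

The engine is a first-order Monte-Carlo Markov microsimulation with a
1-year cycle and no half-cycle correction (outcomes are reported as
annual counts, so cycle-boundary accounting matches the reporting
unit).  Individuals enter with sex and exact age sampled from the
bundle's age–sex population table (population spread uniformly within
each band), a smoking state sampled from the stratum prevalences, and
chronic disease states seeded from a steady-state approximation
(below).  Everyone still alive at age 109 dies of background causes at
the end of that cycle.

**Within-cycle event order** (fixed for reproducibility): smoking
transition (cessation for current smokers; initiation for
never-smokers under 35) → per-condition disease events in the
canonical condition order, with acute events immediately exposed to
case fatality → in-state chronic mortality, again in condition order →
background mortality.  A death is attributed to the first cause that
fires; later draws in the same cycle are ignored for that individual.

**Hazard-to-probability conversion**: annual event probability is
`1 − exp(−h · RR(state))`.  Former smokers carry a single constant
`rr_former` per condition (no decay in time since quitting); this is a
bundle parameter, not a code constant, so a decay curve can be
emulated by stratifying the bundle if needed.

**Acute vs chronic conditions.**  Myocardial infarction, stroke, and
pneumonia are recurrent acute events: each year in which the event
hazard fires counts one event, case fatality is applied, and the
disability exposure of the event is its mean duration.  All other
conditions are absorbing chronic states: the incidence hazard governs
onset, and an in-state annual mortality hazard (independent of smoking
state — the smoking effect enters at onset) governs disease death.

**Baseline chronic prevalence.**  A cross-sectional cohort must start
with prevalent chronic disease, otherwise chronic deaths in the
snapshot year would be near zero.  At entry, each chronic state is
seeded with probability `1 − exp(−h·RR·S)` where `S` is the condition's
mean sojourn, estimated as `1 / (population-mean in-state mortality)`
capped at 25 years.  This is the steady-state prevalence ≈ incidence ×
duration identity.  One consequence: annual cause deaths scale with
*incidence* (prevalence × mortality ≈ incidence/mortality × mortality),
which is why calibration adjusts incidence hazards (below).

**Common random numbers.**  Every cycle draws an `(n, 3K+2)` uniform
matrix in a fixed, state-independent layout regardless of who is
alive, and entry sampling draws a fixed sequence before the first
cycle.  A factual run, a never-smoker counterfactual, and any policy
run with the same seed therefore consume identical randomness, so
differences between runs isolate the modelled effect, and with all
RR ≥ 1 the factual run pathwise dominates the counterfactual.
Competing causes can still make an individual cell (a later-ordered
condition) locally negative — the first-firing cause wins — so
attributable differences are floored at zero cell-by-cell.

## Burden accounting

Annual burden tables report simulation-year-0 outcomes of the
population snapshot for ages 35+, scaled by
`national population / n simulated`.  YLL uses period life-table
residual expectancy at the age of death, undiscounted; YLD is
disability weight × person-years lived in the disease state during the
year (acute events contribute weight × mean duration).  DALY =
YLL + YLD holds exactly by construction, and the report layer enforces
it rather than reproducing any internally inconsistent printed
decomposition.  Counts are rounded half-up to integers and fractions
to one decimal only at report time.

The secondhand-smoke/perinatal uplift (12% of the female, 13.6% of the
male attributable totals) applies to deaths, DALYs, and costs, not to
condition-specific events, whose uplift cells are not applicable.

## Economics

All unit treatment costs are stored in 2015 local currency; the
economics module inflates them by the configured factor (default
+10.47%) and converts at the configured exchange rate (default 3.3
local units per USD).  Wages come from a sex-specific Mincer equation
(log-wage linear in education, quadratic in age) fitted on survey-era
data and are treated as reporting-year currency, so only conversion
applies to them.

- Premature-mortality cost counts only attributable deaths before the
  sex-specific retirement age (65 men / 60 women by default) and
  values each at the present value of future labor income with wage
  growth g (default 2%/yr) and discount rate r (default 5%/yr):
  `Σ_t wage(age+t)·(1+g)^t/(1+r)^t` to retirement.  Discounting
  applies to monetary streams only, never to health outcomes.
- Presenteeism is restricted to working ages (35 to retirement) and is
  proportional to the condition's quality-of-life decrement, for which
  the disability weight is reused.
- Informal care is caregiving hours per case-year valued at a
  care-worker hourly wage.

Reports aggregate the sixteen conditions into seven groups (COPD;
cardiovascular = AMI + other ischemic + non-ischemic heart disease;
lung cancer; other cancers; secondhand smoke/other; stroke;
pneumonia).  Conservation — grand total = Σ categories = Σ groups —
holds before rounding.  Monetary outputs are always labelled millions
of 2020 USD.

## Policy scenarios

`prev_post = prev_pre(1 − Em·Ip)` with Ip defaulting to 0.5.  Moved
smokers are reassigned current → former (quitting does not erase
history).  For tax scenarios `Em = min(1, |elasticity| × price rise)`
— a constant-elasticity approximation.  The default elasticity −0.4 is
a typical low/middle-income value and **not** a country estimate; the
effectiveness values shipped for packaging / smoke-free / advertising
scenarios are placeholders with wide uncertainty ranges, because no
country-calibrated values are distributed with this package.  Benefits
are cumulated undiscounted over a 10-year horizon in a steady state
(fixed population, costs, wages); smoke-free scenarios additionally
scale the secondhand-smoke row by the assumed nonsmoker risk
reduction.  Tax-revenue change assumes the tax absorbs the entire
price increase.

## Calibration

Cells are cause × sex annual deaths (age bands can be added by raising
`n`; at the default n = 50,000 band-level counts are too sparse).  A
cell passes at |relative deviation| ≤ 15%.  Failing cells multiply the
condition-sex incidence hazards by `1 + 0.5(ref/model − 1)` — damping
0.5 guards against Monte-Carlo oscillation — and the model is
re-simulated at the *same seed*, so convergence is to that seed's
realisation; validation should re-run at a different seed.  A cell is
calibratable only when its reference count is at least 7 ≈ 1/0.15:
below that the ±15% band is narrower than one integer death and no
hazard adjustment can land inside it; such cells are reported as not
applicable.  Relative risks are never adjusted, so calibration cannot
silently change the smoking effect.

## Synthetic-data generator

The generator emulates the role of a national parameter appendix; it
is not fitted to any registry.  Choices:

- declining age pyramid (exponential density, slight female excess at
  old ages), total population 33 million;
- current-smoker prevalence 11.6% (men) / 2.6% (women) — the published
  age-adjusted rates; former-smoker prevalence 28% / 8%, reflecting
  the much higher smoking of past decades in the cohorts now old
  enough to bear the burden (this is what lets attributable fractions
  reach realistic magnitudes at today's low current prevalence);
- never-smoker hazards follow Gompertz age-shapes with
  condition-specific slopes, plateauing at age 85 (cancer and
  cardiovascular incidence flattens at the oldest ages; the plateau
  also prevents prevalence saturation from compressing attributable
  fractions), with bases scaled so per-condition annual deaths land on
  the published order of magnitude for a 33-million population;
- relative risks sit in the literature ranges for smoking:
  cardiovascular 1.5–3, respiratory 5–15, lung and laryngeal cancer
  10–25 (current), with former-smoker risks about half;
- background mortality is a separate Gompertz hazard representing
  causes outside the sixteen conditions; residual life expectancy is
  derived from it alone, a deliberate simplification that slightly
  overstates YLL per death;
- mild log-normal jitter (σ = 0.05) on incidence bases makes bundles
  differ across seeds while always validating.

What the generator does **not** emulate: cohort-specific smoking
histories, geographic heterogeneity, condition interactions beyond
shared mortality, trends in any input.  Tests passing on synthetic
bundles therefore demonstrate the correctness of the machinery — the
arithmetic, the ordering properties, the calibration contract — not
the accuracy of any real country estimate.

## Problem sizes and determinism

Default sizes were chosen to keep estimates statistically meaningful:
n = 50,000 for burden/cost pipelines and calibration, n = 100,000 for
policy dose-response comparisons, and n = 500,000 with a 4-year death
window for the lung-cancer attributable-fraction measurement (about
200+ attributable deaths, ±3 percentage points).  Every random draw
descends from a single `numpy` PCG64 generator seeded by the
user-supplied seed; identical (model, n, seed, mode) reproduce results
bit-for-bit, and the pipeline manifest records everything needed to
regenerate each table.

## Known limitations

- Former-smoker risk does not decay with time since quitting.
- The engine has no births or migration; 10-year projections follow a
  closed cross-sectional cohort, which understates burden in later
  projection years relative to a stationary population.
- Death-cause attribution uses a fixed condition order, which slightly
  favours earlier-ordered conditions among multimorbid individuals.
- Presenteeism reuses the disability weight as the productivity
  decrement; absenteeism and environmental costs are out of scope.
- The fixed secondhand-smoke uplift is a proportional add-on, not a
  modelled exposure.
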