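"""Synthetic country-parameter bundles.

The real model inputs for a country (registry hazards, literature
relative risks, costed treatment protocols) are not shipped with this
package, so every stage is exercised against internally consistent
synthetic bundles.  :func:`generate_country` builds one from a handful
of targets: a declining age pyramid, sex-specific smoking prevalence
(defaults: 11.6% of men and 2.6% of women are current smokers, the
published age-adjusted rates for Peru), Gompertz-shaped never-smoker
hazards per condition, relative risks drawn from the ranges reported
for smoking (cardiovascular ~1.5-3, respiratory ~5-15, lung and
laryngeal cancer ~10-25), and plausible unit costs, disability weights,
and care hours.

The default configuration is the package's "Peru-like" fixture.  It is
a stand-in with the published prevalence and attributable-fraction
magnitudes, not a reproduction of the original country parameters,
which were never deposited.

:func:`printed_counts_fixture` returns the published annual burden and
cost report cells (counts and millions of USD) verbatim; they are
report-layer inputs for arithmetic checks, not simulation outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    CONDITION_IDS,
    SEXES,
    CountryModel,
    DiseaseSpec,
    EconomicParams,
    SmokingProfile,
    validate_model,
)

# per-condition generator parameters:
# (acute, inc35 per py, inc slope /yr, male multiplier, chronic in-state
#  death hazard, case fatality, dw, duration yrs, cost 2015 PEN/yr,
#  care h/yr, rr_current, rr_former)
_DISEASE_PARAMS = {
    "ami":                  (True,  4.7e-5, 0.075, 1.6, 0.0,  0.30, 0.12, 0.5, 15000, 150, 2.5, 1.5),
    "ihd":                  (False, 2.4e-6, 0.070, 1.5, 0.06, 0.0,  0.08, 8.0,  6000, 200, 2.2, 1.4),
    "nihd":                 (False, 1.0e-5, 0.080, 1.2, 0.07, 0.0,  0.10, 7.0,  6500, 250, 1.6, 1.2),
    "stroke":               (True,  7.4e-5, 0.080, 1.2, 0.0,  0.25, 0.30, 2.0, 12000, 800, 2.0, 1.3),
    "pneumonia":            (True,  2.9e-4, 0.085, 1.1, 0.0,  0.10, 0.10, 0.1,  3000,  40, 5.0, 2.0),
    "copd":                 (False, 2.7e-5, 0.080, 1.2, 0.08, 0.0,  0.35, 10.0, 8000, 500, 13.0, 7.0),
    "lung_cancer":          (False, 2.4e-6, 0.080, 1.3, 0.45, 0.0,  0.45, 2.0, 35000, 600, 24.0, 12.0),
    "oropharyngeal_cancer": (False, 1.9e-6, 0.060, 1.8, 0.25, 0.0,  0.35, 3.0, 25000, 400, 8.0, 4.0),
    "esophageal_cancer":    (False, 6.6e-7, 0.065, 1.7, 0.45, 0.0,  0.45, 2.0, 30000, 500, 6.0, 3.0),
    "stomach_cancer":       (False, 1.3e-5, 0.070, 1.4, 0.35, 0.0,  0.40, 2.5, 28000, 450, 2.0, 1.5),
    "pancreatic_cancer":    (False, 7.0e-6, 0.070, 1.1, 0.60, 0.0,  0.45, 1.2, 32000, 500, 2.2, 1.5),
    "renal_cancer":         (False, 6.4e-6, 0.060, 1.6, 0.20, 0.0,  0.35, 4.0, 26000, 350, 2.4, 1.6),
    "laryngeal_cancer":     (False, 1.5e-7, 0.060, 2.0, 0.25, 0.0,  0.35, 3.0, 24000, 350, 21.0, 10.5),
    "cervical_cancer":      (False, 1.0e-4, 0.030, 0.0, 0.20, 0.0,  0.30, 4.0, 22000, 350, 2.2, 1.4),
    "bladder_cancer":       (False, 8.3e-7, 0.070, 2.2, 0.15, 0.0,  0.30, 5.0, 23000, 300, 3.5, 2.0),
    "leukemia":             (False, 1.4e-5, 0.045, 1.1, 0.30, 0.0,  0.40, 3.0, 40000, 500, 1.8, 1.4),
}

_ICD10 = {
    "ami": "I210-I229",
    "ihd": "I200-I209",
    "nihd": "I300-I528",
    "stroke": "I60-I64;I69",
    "pneumonia": "J100-J189",
    "copd": "J400-J449",
    "lung_cancer": "C330-C349",
    "oropharyngeal_cancer": "C000-C148",
    "esophageal_cancer": "C150-C159",
    "stomach_cancer": "C160-C169",
    "pancreatic_cancer": "C250-C259",
    "renal_cancer": "C64-C65",
    "laryngeal_cancer": "C320-C329",
    "cervical_cancer": "C530-C539",
    "bladder_cancer": "C670-C679",
    "leukemia": "C920",
}


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic bundle generator."""

    seed: int = 20
    population_scale: float = 33_000_000.0
    prev_current: dict = field(default_factory=lambda: {"male": 0.116, "female": 0.026})
    # former-smoker share reflects the much higher smoking prevalence of
    # past decades among the cohorts now old enough to bear the burden
    prev_former: dict = field(default_factory=lambda: {"male": 0.28, "female": 0.08})
    severity_scale: float = 1.0
    cost_scale: float = 1.0
    noise_level: float = 0.05
    gdp_musd: float = 202_000.0


def _age_bands() -> list[tuple[int, int]]:
    bands = [(15, 24), (25, 34)]
    bands += [(lo, lo + 4) for lo in range(35, 95, 5)]
    bands.append((95, 109))
    return bands


def generate_country(config: GeneratorConfig | None = None) -> CountryModel:
    """Build a complete, validated synthetic CountryModel.

    Deterministic in ``config.seed``.  Raises ValueError for impossible
    prevalence targets (current + former > 1).
    """
    config = config or GeneratorConfig()
    for sex in SEXES:
        pc, pf = config.prev_current[sex], config.prev_former[sex]
        if not (0 <= pc <= 1 and 0 <= pf <= 1 and pc + pf <= 1):
            raise ValueError(f"impossible smoking prevalence targets for {sex}")

    rng = np.random.default_rng(config.seed)
    bands = _age_bands()

    # declining age pyramid, slightly more women at old ages
    strata_rows = []
    for sex in SEXES:
        for lo, hi in bands:
            mid = 0.5 * (lo + hi)
            base = np.exp(-0.028 * (mid - 15))
            sex_adj = 1.0 if sex == "male" else 1.0 + 0.003 * max(mid - 60, 0)
            pop = config.population_scale * 0.011 * base * (hi - lo + 1) * sex_adj
            strata_rows.append(
                {
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "population": round(pop),
                    "education_years": 10.0 if sex == "male" else 9.5,
                }
            )
    strata = pd.DataFrame(strata_rows)

    smoking_rows = []
    for sex in SEXES:
        for lo, hi in bands:
            pc = config.prev_current[sex]
            pf = config.prev_former[sex] if lo >= 35 else config.prev_former[sex] * 0.3
            smoking_rows.append(
                {
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "prev_current": pc,
                    "prev_former": pf,
                    "prev_never": 1.0 - pc - pf,
                }
            )
    smoking = SmokingProfile(pd.DataFrame(smoking_rows))

    diseases = []
    hazard_rows = []
    for cid in CONDITION_IDS:
        (acute, inc35, slope, male_mult, chronic_mort, cf, dw, dur,
         cost, care_h, rr_c, rr_f) = _DISEASE_PARAMS[cid]
        # mild condition-level noise so bundles differ across seeds
        jitter = float(np.exp(rng.normal(0.0, config.noise_level)))
        inc35 = inc35 * config.severity_scale * jitter
        diseases.append(
            DiseaseSpec(
                condition_id=cid,
                icd10_codes=_ICD10[cid],
                acute=acute,
                rr_current=rr_c,
                rr_former=rr_f,
                case_fatality=cf,
                disability_weight=dw,
                mean_duration_years=dur,
                annual_direct_cost=cost * config.cost_scale,
                informal_care_hours_per_year=care_h,
                event_af_computable=(cid != "nihd"),
                women_only=(cid == "cervical_cancer"),
            )
        )
        for sex in SEXES:
            mult = male_mult if sex == "male" else 1.0
            if cid == "cervical_cancer":
                mult = 0.0 if sex == "male" else 1.0
            for lo, hi in bands:
                mid = 0.5 * (lo + hi)
                # Gompertz growth, plateauing at age 85 (incidence of most
                # smoking-related conditions flattens at the oldest ages)
                growth = np.exp(slope * min(max(mid - 35, 0.0), 50.0)) if mid >= 35 else 0.0
                inc = inc35 * mult * growth
                mort = chronic_mort * (1.0 + 0.01 * max(mid - 35, 0.0)) if not acute else 0.0
                hazard_rows.append(
                    {
                        "condition_id": cid,
                        "sex": sex,
                        "age_lo": lo,
                        "age_hi": hi,
                        "incidence": inc,
                        "mortality": mort if inc > 0 or not acute else 0.0,
                    }
                )
    hazards = pd.DataFrame(hazard_rows)

    # background (other-cause) Gompertz mortality and the residual life
    # expectancy implied by it
    lt_rows = []
    for sex in SEXES:
        sex_mult = 1.15 if sex == "male" else 1.0
        ages = np.arange(15, 110)
        mu = 1.2e-3 * sex_mult * np.exp(0.07 * np.maximum(ages - 35, 0.0))
        # residual LE from the discrete survival curve of mu
        surv = np.concatenate([[1.0], np.cumprod(np.exp(-mu))])
        res_le = np.array(
            [surv[i + 1 :].sum() / surv[i] if surv[i] > 0 else 0.0 for i in range(len(ages))]
        )
        for lo, hi in bands:
            sel = (ages >= lo) & (ages <= hi)
            lt_rows.append(
                {
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "hazard": float(mu[sel].mean()),
                    "residual_le": float(res_le[sel].mean()),
                }
            )
    life_table = pd.DataFrame(lt_rows)

    econ = EconomicParams(gdp_musd=config.gdp_musd)

    model = CountryModel(
        strata=strata,
        smoking=smoking,
        diseases=diseases,
        hazards=hazards,
        life_table=life_table,
        econ=econ,
        shs_uplift={"male": 0.136, "female": 0.12},
    )
    issues = validate_model(model)
    if issues:  # pragma: no cover - generator bug guard
        raise AssertionError("generator produced an invalid model:\n" + "\n".join(issues))
    return model


def peru_like_fixture(seed: int = 20) -> CountryModel:
    """The default synthetic bundle with published Peruvian prevalences."""
    return generate_country(GeneratorConfig(seed=seed))


def perturb(model: CountryModel, seed: int, magnitude: float) -> CountryModel:
    """Multiply all condition hazards by log-normal noise.

    ``magnitude`` is the sigma of the log-normal factor; 0 returns an
    identical model.  The output still validates.
    """
    if not (0 <= magnitude < 1):
        raise ValueError("magnitude must be in [0,1)")
    out = model.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, magnitude, size=len(out.hazards)))
    out.hazards = out.hazards.assign(
        incidence=out.hazards["incidence"] * factors,
        mortality=out.hazards["mortality"] * factors,
    )
    issues = validate_model(out)
    if issues:  # pragma: no cover
        raise AssertionError("perturbed model invalid:\n" + "\n".join(issues))
    return out


def printed_counts_fixture() -> dict:
    """Published annual report cells, as report-layer test inputs.

    ``deaths`` has per-condition national totals, attributable counts
    (total/men/women), and the printed attributable percentage.
    ``cost_categories`` / ``cost_groups`` are millions of 2020 USD.
    """
    deaths = pd.DataFrame(
        [
            ("ami", 6348, 1303, 841, 462, 20.5),
            ("ihd", 794, 189, 121, 68, 23.9),
            ("nihd", 4599, 759, 530, 228, 16.5),
            ("stroke", 8288, 1538, 912, 626, 18.6),
            ("lung_cancer", 2910, 2420, 1324, 1096, 83.2),
            ("pneumonia", 13719, 2874, 1684, 1190, 21.0),
            ("copd", 9517, 7625, 3910, 3715, 80.1),
            ("oropharyngeal_cancer", 565, 368, 231, 137, 65.1),
            ("esophageal_cancer", 366, 260, 186, 74, 71.3),
            ("stomach_cancer", 4692, 1041, 749, 292, 22.2),
            ("pancreatic_cancer", 1561, 457, 242, 215, 29.3),
            ("renal_cancer", 808, 237, 221, 16, 29.4),
            ("laryngeal_cancer", 136, 115, 86, 29, 84.6),
            ("leukemia", 1204, 209, 153, 56, 17.4),
            ("bladder_cancer", 384, 165, 122, 43, 43.0),
            ("cervical_cancer", 1811, 236, 0, 236, 13.0),
        ],
        columns=["condition", "total", "attributable", "att_men", "att_women", "printed_pct"],
    )
    totals = {
        "total_deaths": 60275,
        "attributable_deaths": 22353,
        "attributable_deaths_pct": 37.1,
        "total_events": 321840,
        "attributable_events": 125996,
        "attributable_events_pct": 39.1,
        "shs_deaths": 2574,
    }
    cost_categories = {
        "direct_medical": 1285.2,
        "premature_mortality": 325.1,
        "disability": 453.0,
        "informal_care": 740.5,
    }
    cost_groups = {
        "copd": 1193.8,
        "cardiovascular": 273.3,
        "lung_cancer": 227.7,
        "other_cancers": 365.0,
        "shs_other": 320.6,
        "stroke": 391.1,
        "pneumonia": 32.2,
    }
    return {
        "deaths": deaths,
        "totals": totals,
        "cost_categories": cost_categories,
        "cost_groups": cost_groups,
        "gdp_share_total_pct": 1.28,
        "gdp_share_direct_pct": 0.59,
    }
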