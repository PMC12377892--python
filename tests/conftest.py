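import numpy as np
import pandas as pd
import pytest

from tobacco_burden.parameters import (
    CONDITION_IDS,
    SEXES,
    CountryModel,
    DiseaseSpec,
    EconomicParams,
    SmokingProfile,
)
from tobacco_burden.microsim import simulate_population
from tobacco_burden.synthetic_data import peru_like_fixture


def make_toy_model(
    incidence: float = 0.0,
    case_fatality: float = 0.0,
    background: float = 0.02,
    active_condition: str = "ami",
    prev_current: float = 0.3,
    prev_former: float = 0.1,
    rr_current: float = 2.0,
    rr_former: float = 1.5,
    chronic_mortality: float = 0.0,
    age_band: tuple[int, int] = (35, 44),
    cessation: float = 0.0,
) -> CountryModel:
    """Minimal model: one age band, one active condition, constant hazards.

    All other conditions get zero hazards, which makes closed-form
    Markov-chain oracles tractable.
    """
    lo, hi = age_band
    strata = pd.DataFrame(
        [
            {"sex": s, "age_lo": lo, "age_hi": hi, "population": 1000.0,
             "education_years": 10.0}
            for s in SEXES
        ]
    )
    smoking = SmokingProfile(
        pd.DataFrame(
            [
                {"sex": s, "age_lo": lo, "age_hi": hi,
                 "prev_current": prev_current, "prev_former": prev_former,
                 "prev_never": 1.0 - prev_current - prev_former}
                for s in SEXES
            ]
        ),
        cessation_prob=cessation,
        initiation_prob=0.0,
    )
    diseases, hazard_rows = [], []
    for cid in CONDITION_IDS:
        active = cid == active_condition
        diseases.append(
            DiseaseSpec(
                condition_id=cid,
                icd10_codes="X",
                acute=(chronic_mortality == 0.0) if active else True,
                rr_current=rr_current if active else 1.0,
                rr_former=rr_former if active else 1.0,
                case_fatality=case_fatality if active else 0.0,
                disability_weight=0.2 if active else 0.0,
                mean_duration_years=1.0,
                annual_direct_cost=1000.0 if active else 0.0,
                informal_care_hours_per_year=100.0 if active else 0.0,
                event_af_computable=(cid != "nihd"),
            )
        )
        for s in SEXES:
            # hazards stay constant all the way to the age cap so the
            # chain is homogeneous even as entrants age out of the band
            hazard_rows.append(
                {"condition_id": cid, "sex": s, "age_lo": lo, "age_hi": 109,
                 "incidence": incidence if active else 0.0,
                 "mortality": chronic_mortality if active else 0.0}
            )
    life_table = pd.DataFrame(
        [
            {"sex": s, "age_lo": lo, "age_hi": 109,
             "hazard": background, "residual_le": 10.0}
            for s in SEXES
        ]
    )
    return CountryModel(
        strata=strata,
        smoking=smoking,
        diseases=diseases,
        hazards=pd.DataFrame(hazard_rows),
        life_table=life_table,
        econ=EconomicParams(),
        shs_uplift={"male": 0.136, "female": 0.12},
    )


@pytest.fixture(scope="session")
def peru_model():
    return peru_like_fixture()


@pytest.fixture(scope="session")
def paired_lifetime(peru_model):
    """Factual + never-smoker lifetime runs sharing seed (common random numbers)."""
    n, seed = 20_000, 7
    factual = simulate_population(peru_model, n, seed, "factual", "lifetime")
    never = simulate_population(peru_model, n, seed, "never_smoker", "lifetime")
    return factual, never
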