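"""Country parameter bundle: domain types, I/O, and validation.

A *bundle* is a directory of delimited tables plus one YAML config that
together describe everything the simulation needs for one country:

``strata.csv``
    Age-sex population structure (5-year bands from 35, coarse bands
    below 35 for initiation dynamics) and mean years of education.
``smoking.csv``
    Current/former/never smoking prevalence per stratum.
``diseases.csv``
    One row per modelled condition: relative risks, case fatality,
    disability weight, unit costs, informal-care hours.
``hazards.csv``
    Never-smoker incidence and in-state mortality hazards per
    condition, sex, and age band (per person-year).
``life_table.csv``
    Background (other-cause) mortality hazard and residual life
    expectancy per sex and age band.
``config.yaml``
    Scalar parameters: smoking dynamics, economics, secondhand-smoke
    uplift.

All monetary unit costs are stored in 2015 local currency; conversion
to 2020 USD happens only in :mod:`tobacco_burden.economics`.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

SEXES = ("male", "female")

#: Canonical condition identifiers, in simulation order.
CONDITION_IDS = (
    "ami",
    "ihd",
    "nihd",
    "stroke",
    "pneumonia",
    "copd",
    "lung_cancer",
    "oropharyngeal_cancer",
    "esophageal_cancer",
    "stomach_cancer",
    "pancreatic_cancer",
    "renal_cancer",
    "laryngeal_cancer",
    "cervical_cancer",
    "bladder_cancer",
    "leukemia",
)

CONDITION_LABELS = {
    "ami": "Acute myocardial infarction",
    "ihd": "Ischemic heart disease (non-AMI)",
    "nihd": "Non-ischemic heart disease",
    "stroke": "Stroke",
    "pneumonia": "Pneumonia",
    "copd": "COPD",
    "lung_cancer": "Lung cancer",
    "oropharyngeal_cancer": "Oropharyngeal cancer",
    "esophageal_cancer": "Esophageal cancer",
    "stomach_cancer": "Stomach cancer",
    "pancreatic_cancer": "Pancreatic cancer",
    "renal_cancer": "Kidney cancer",
    "laryngeal_cancer": "Laryngeal cancer",
    "cervical_cancer": "Cervical cancer",
    "bladder_cancer": "Bladder cancer",
    "leukemia": "Leukemia",
}

#: Seven reporting groups used by the cost tables (the secondhand-smoke
#: group is added at report time, not mapped from a condition).
CONDITION_GROUPS = {
    "ami": "cardiovascular",
    "ihd": "cardiovascular",
    "nihd": "cardiovascular",
    "stroke": "stroke",
    "pneumonia": "pneumonia",
    "copd": "copd",
    "lung_cancer": "lung_cancer",
    "oropharyngeal_cancer": "other_cancers",
    "esophageal_cancer": "other_cancers",
    "stomach_cancer": "other_cancers",
    "pancreatic_cancer": "other_cancers",
    "renal_cancer": "other_cancers",
    "laryngeal_cancer": "other_cancers",
    "cervical_cancer": "other_cancers",
    "bladder_cancer": "other_cancers",
    "leukemia": "other_cancers",
}

GROUP_ORDER = (
    "copd",
    "cardiovascular",
    "lung_cancer",
    "other_cancers",
    "shs_other",
    "stroke",
    "pneumonia",
)

GROUP_LABELS = {
    "copd": "COPD",
    "cardiovascular": "Cardiovascular diseases",
    "lung_cancer": "Lung cancer",
    "other_cancers": "Other cancers",
    "shs_other": "Secondhand smoke and other causes",
    "stroke": "Stroke",
    "pneumonia": "Pneumonia",
}


class ParameterError(Exception):
    """A bundle could not be loaded (missing table, column, or value)."""


class ValidationError(ParameterError):
    """A loaded bundle violates one or more model invariants."""

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__(
            "invalid country model:\n" + "\n".join(f"  - {i}" for i in issues)
        )


@dataclass(frozen=True)
class DiseaseSpec:
    """One smoking-related condition.

    ``rr_current``/``rr_former`` multiply the never-smoker incidence
    hazard.  For acute conditions (``acute=True``) deaths arise from
    events via ``case_fatality``; chronic conditions are absorbing
    disease states whose in-state annual death hazard is given in the
    hazards table.  ``annual_direct_cost`` is per case-year in 2015
    local currency.
    """

    condition_id: str
    icd10_codes: str
    acute: bool
    rr_current: float
    rr_former: float
    case_fatality: float
    disability_weight: float
    mean_duration_years: float
    annual_direct_cost: float
    informal_care_hours_per_year: float
    event_af_computable: bool = True
    women_only: bool = False

    @property
    def label(self) -> str:
        return CONDITION_LABELS.get(self.condition_id, self.condition_id)

    @property
    def group(self) -> str:
        return CONDITION_GROUPS[self.condition_id]


@dataclass(frozen=True)
class EconomicParams:
    """Scalar economic parameters.

    Rates are fractions (``inflation_factor=0.1047`` means +10.47%
    between the costing year and the reporting year).  Mincer
    coefficients are per sex: log-wage intercept, return to a year of
    education, and a quadratic age profile.  ``prevalence_impact_share``
    is the fraction of a policy-induced consumption drop expressed as
    lower smoker prevalence (Ip).
    """

    exchange_rate_pen_per_usd: float = 3.3
    inflation_factor: float = 0.1047
    discount_rate: float = 0.05
    wage_growth_rate: float = 0.02
    retirement_age: dict = field(
        default_factory=lambda: {"male": 65, "female": 60}
    )
    mincer: dict = field(
        default_factory=lambda: {
            "male": {"beta0": 7.5, "beta_edu": 0.09, "beta_age": 0.06, "beta_age2": -0.0006},
            "female": {"beta0": 7.3, "beta_edu": 0.09, "beta_age": 0.055, "beta_age2": -0.00055},
        }
    )
    mean_education_years: dict = field(
        default_factory=lambda: {"male": 10.0, "female": 9.5}
    )
    caregiver_hourly_wage: float = 8.0
    prevalence_impact_share: float = 0.5
    gdp_musd: float | None = None
    pack_price: float = 10.0
    tax_share: float = 0.733
    baseline_packs_millions: float = 125.0


@dataclass
class SmokingProfile:
    """Smoking prevalence per stratum plus annual transition probabilities."""

    table: pd.DataFrame  # sex, age_lo, age_hi, prev_current, prev_former, prev_never
    cessation_prob: float = 0.03
    initiation_prob: float = 0.01


@dataclass
class CountryModel:
    """The full parameter bundle driving every pipeline stage."""

    strata: pd.DataFrame  # sex, age_lo, age_hi, population, education_years
    smoking: SmokingProfile
    diseases: list
    hazards: pd.DataFrame  # condition_id, sex, age_lo, age_hi, incidence, mortality
    life_table: pd.DataFrame  # sex, age_lo, age_hi, hazard, residual_le
    econ: EconomicParams
    shs_uplift: dict = field(default_factory=lambda: {"male": 0.136, "female": 0.12})

    def disease(self, condition_id: str) -> DiseaseSpec:
        for d in self.diseases:
            if d.condition_id == condition_id:
                return d
        raise KeyError(condition_id)

    @property
    def total_population(self) -> float:
        return float(self.strata["population"].sum())

    def copy(self) -> "CountryModel":
        return CountryModel(
            strata=self.strata.copy(),
            smoking=SmokingProfile(
                self.smoking.table.copy(),
                self.smoking.cessation_prob,
                self.smoking.initiation_prob,
            ),
            diseases=list(self.diseases),
            hazards=self.hazards.copy(),
            life_table=self.life_table.copy(),
            econ=dataclasses.replace(self.econ),
            shs_uplift=dict(self.shs_uplift),
        )


# ---------------------------------------------------------------------------
# validation

def _check_bands(df: pd.DataFrame, name: str, issues: list[str]) -> None:
    for sex in SEXES:
        sub = df[df["sex"] == sex].sort_values("age_lo")
        if sub.empty:
            issues.append(f"{name}: no rows for sex={sex}")
            continue
        prev_hi = None
        for _, row in sub.iterrows():
            lo, hi = int(row["age_lo"]), int(row["age_hi"])
            if hi < lo:
                issues.append(f"{name}: band [{lo},{hi}] for {sex} has hi < lo")
            if prev_hi is not None:
                if lo <= prev_hi:
                    issues.append(
                        f"{name}: bands overlap at age {lo} for sex={sex}"
                    )
                elif lo != prev_hi + 1:
                    issues.append(
                        f"{name}: gap between ages {prev_hi} and {lo} for sex={sex}"
                    )
            prev_hi = hi


def validate_model(model: CountryModel) -> list[str]:
    """Check every model invariant; return a list of human-readable issues.

    Never raises: an empty list means the model is valid.
    """
    issues: list[str] = []

    # strata
    _check_bands(model.strata, "strata", issues)
    if (model.strata["population"] < 0).any():
        bad = model.strata[model.strata["population"] < 0]
        for _, r in bad.iterrows():
            issues.append(
                f"strata: negative population in {r['sex']} [{r['age_lo']},{r['age_hi']}]"
            )

    # smoking
    sm = model.smoking.table
    for _, r in sm.iterrows():
        tag = f"{r['sex']} [{int(r['age_lo'])},{int(r['age_hi'])}]"
        probs = [r["prev_current"], r["prev_former"], r["prev_never"]]
        if any((p < 0) or (p > 1) for p in probs):
            issues.append(f"smoking: prevalence outside [0,1] in {tag}")
        if abs(sum(probs) - 1.0) > 1e-9:
            issues.append(
                f"smoking: prevalences sum to {sum(probs):.6f} != 1 in {tag}"
            )
    for pname in ("cessation_prob", "initiation_prob"):
        p = getattr(model.smoking, pname)
        if not (0 <= p <= 1):
            issues.append(f"smoking: {pname}={p} outside [0,1]")

    # diseases
    seen = [d.condition_id for d in model.diseases]
    for cid in CONDITION_IDS:
        if cid not in seen:
            issues.append(f"diseases: missing condition {cid}")
    for cid in seen:
        if seen.count(cid) > 1:
            issues.append(f"diseases: duplicate condition {cid}")
    for d in model.diseases:
        if d.rr_current < 0 or d.rr_former < 0:
            issues.append(f"diseases: negative relative risk for {d.condition_id}")
        if d.rr_current > 1 and d.rr_former > 1 and d.rr_former > d.rr_current:
            issues.append(
                f"diseases: rr_former > rr_current for {d.condition_id}"
            )
        if not (0 <= d.disability_weight <= 1):
            issues.append(
                f"diseases: disability_weight outside [0,1] for {d.condition_id}"
            )
        if not (0 <= d.case_fatality <= 1):
            issues.append(
                f"diseases: case_fatality outside [0,1] for {d.condition_id}"
            )
        if d.mean_duration_years <= 0:
            issues.append(
                f"diseases: mean_duration_years <= 0 for {d.condition_id}"
            )
        if d.annual_direct_cost < 0:
            issues.append(f"diseases: negative unit cost for {d.condition_id}")
        if d.informal_care_hours_per_year < 0:
            issues.append(f"diseases: negative care hours for {d.condition_id}")

    # hazards
    hz = model.hazards
    if (hz["incidence"] < 0).any() or (hz["mortality"] < 0).any():
        for _, r in hz[(hz["incidence"] < 0) | (hz["mortality"] < 0)].iterrows():
            issues.append(
                f"hazards: negative hazard for {r['condition_id']} "
                f"{r['sex']} [{int(r['age_lo'])},{int(r['age_hi'])}]"
            )
    have = set(hz["condition_id"].unique())
    for cid in CONDITION_IDS:
        if cid in seen and cid not in have:
            issues.append(f"hazards: no hazard rows for condition {cid}")

    # life table
    lt = model.life_table
    if (lt["hazard"] < 0).any():
        issues.append("life_table: negative mortality hazard")
    for sex in SEXES:
        sub = lt[lt["sex"] == sex].sort_values("age_lo")
        le = sub["residual_le"].to_numpy()
        if len(le) > 1 and not np.all(np.diff(le) < 0):
            issues.append(
                f"life_table: residual life expectancy not strictly decreasing for {sex}"
            )
    _check_bands(lt, "life_table", issues)

    # economics
    e = model.econ
    if e.exchange_rate_pen_per_usd <= 0:
        issues.append("econ: exchange rate must be > 0")
    for rname in ("inflation_factor", "discount_rate", "wage_growth_rate"):
        r = getattr(e, rname)
        if not (0 <= r < 1):
            issues.append(f"econ: {rname}={r} outside [0,1)")
    for sex in SEXES:
        if e.retirement_age.get(sex, 0) <= 35:
            issues.append(f"econ: retirement age for {sex} must be > 35")
    if not (0 <= e.prevalence_impact_share <= 1):
        issues.append("econ: prevalence_impact_share outside [0,1]")

    for sex, u in model.shs_uplift.items():
        if u < 0:
            issues.append(f"shs_uplift: negative uplift for {sex}")

    return issues


# ---------------------------------------------------------------------------
# I/O

_TABLES = {
    "strata": ["sex", "age_lo", "age_hi", "population", "education_years"],
    "smoking": ["sex", "age_lo", "age_hi", "prev_current", "prev_former", "prev_never"],
    "diseases": [
        "condition_id", "icd10_codes", "acute", "rr_current", "rr_former",
        "case_fatality", "disability_weight", "mean_duration_years",
        "annual_direct_cost", "informal_care_hours_per_year",
        "event_af_computable", "women_only",
    ],
    "hazards": ["condition_id", "sex", "age_lo", "age_hi", "incidence", "mortality"],
    "life_table": ["sex", "age_lo", "age_hi", "hazard", "residual_le"],
}


def _read_table(path: pathlib.Path, name: str) -> pd.DataFrame:
    f = path / f"{name}.csv"
    if not f.exists():
        raise ParameterError(f"bundle is missing table '{name}' ({f})")
    df = pd.read_csv(f)
    for col in _TABLES[name]:
        if col not in df.columns:
            raise ParameterError(f"table '{name}' is missing column '{col}'")
    return df


def load_country(path: str | pathlib.Path) -> CountryModel:
    """Load and validate a parameter bundle from a directory.

    Raises :class:`ParameterError` when a table or field is missing and
    :class:`ValidationError` (listing all failures) when the assembled
    model violates an invariant.
    """
    path = pathlib.Path(path)
    if not path.is_dir():
        raise ParameterError(f"bundle directory not found: {path}")

    strata = _read_table(path, "strata")
    smoking_tbl = _read_table(path, "smoking")
    disease_tbl = _read_table(path, "diseases")
    hazards = _read_table(path, "hazards")
    life_table = _read_table(path, "life_table")

    cfg_file = path / "config.yaml"
    if not cfg_file.exists():
        raise ParameterError(f"bundle is missing config.yaml ({cfg_file})")
    with open(cfg_file) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("economics", "smoking", "shs_uplift"):
        if key not in cfg:
            raise ParameterError(f"config.yaml is missing section '{key}'")

    diseases = [
        DiseaseSpec(
            condition_id=r["condition_id"],
            icd10_codes=r["icd10_codes"],
            acute=bool(r["acute"]),
            rr_current=float(r["rr_current"]),
            rr_former=float(r["rr_former"]),
            case_fatality=float(r["case_fatality"]),
            disability_weight=float(r["disability_weight"]),
            mean_duration_years=float(r["mean_duration_years"]),
            annual_direct_cost=float(r["annual_direct_cost"]),
            informal_care_hours_per_year=float(r["informal_care_hours_per_year"]),
            event_af_computable=bool(r["event_af_computable"]),
            women_only=bool(r["women_only"]),
        )
        for _, r in disease_tbl.iterrows()
    ]

    econ_cfg = dict(cfg["economics"])
    gdp = econ_cfg.pop("gdp_musd", None)
    econ = EconomicParams(gdp_musd=gdp, **econ_cfg)

    model = CountryModel(
        strata=strata,
        smoking=SmokingProfile(
            smoking_tbl,
            cessation_prob=float(cfg["smoking"]["cessation_prob"]),
            initiation_prob=float(cfg["smoking"]["initiation_prob"]),
        ),
        diseases=diseases,
        hazards=hazards,
        life_table=life_table,
        econ=econ,
        shs_uplift={k: float(v) for k, v in cfg["shs_uplift"].items()},
    )

    issues = validate_model(model)
    if issues:
        raise ValidationError(issues)
    return model


def save_country(model: CountryModel, path: str | pathlib.Path) -> pathlib.Path:
    """Write a model back out as a bundle directory (inverse of load)."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)

    model.strata.to_csv(path / "strata.csv", index=False)
    model.smoking.table.to_csv(path / "smoking.csv", index=False)
    pd.DataFrame(
        [
            {
                "condition_id": d.condition_id,
                "icd10_codes": d.icd10_codes,
                "acute": d.acute,
                "rr_current": d.rr_current,
                "rr_former": d.rr_former,
                "case_fatality": d.case_fatality,
                "disability_weight": d.disability_weight,
                "mean_duration_years": d.mean_duration_years,
                "annual_direct_cost": d.annual_direct_cost,
                "informal_care_hours_per_year": d.informal_care_hours_per_year,
                "event_af_computable": d.event_af_computable,
                "women_only": d.women_only,
            }
            for d in model.diseases
        ]
    ).to_csv(path / "diseases.csv", index=False)
    model.hazards.to_csv(path / "hazards.csv", index=False)
    model.life_table.to_csv(path / "life_table.csv", index=False)

    e = model.econ
    econ_cfg = {
        "exchange_rate_pen_per_usd": e.exchange_rate_pen_per_usd,
        "inflation_factor": e.inflation_factor,
        "discount_rate": e.discount_rate,
        "wage_growth_rate": e.wage_growth_rate,
        "retirement_age": dict(e.retirement_age),
        "mincer": {s: dict(c) for s, c in e.mincer.items()},
        "mean_education_years": dict(e.mean_education_years),
        "caregiver_hourly_wage": e.caregiver_hourly_wage,
        "prevalence_impact_share": e.prevalence_impact_share,
        "pack_price": e.pack_price,
        "tax_share": e.tax_share,
        "baseline_packs_millions": e.baseline_packs_millions,
    }
    if e.gdp_musd is not None:
        econ_cfg["gdp_musd"] = e.gdp_musd
    cfg = {
        "economics": econ_cfg,
        "smoking": {
            "cessation_prob": model.smoking.cessation_prob,
            "initiation_prob": model.smoking.initiation_prob,
        },
        "shs_uplift": dict(model.shs_uplift),
    }
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
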