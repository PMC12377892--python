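"""Attributable economic burden in 2020 USD.

Four cost categories are computed from the factual-minus-counterfactual
differences of a paired simulation:

direct medical
    attributable person-years in each disease state times the
    condition's annual treatment cost (stored in 2015 local currency,
    adjusted for inflation, then converted to USD);
premature mortality
    human-capital value of attributable deaths before retirement: the
    present value of future labor income from a Mincer wage equation,
    discounted at the configured rate with configured wage growth;
disability (presenteeism)
    working-age attributable case-years times the condition's
    quality-of-life decrement times the age-sex wage (productivity
    loss while working ill is assumed proportional to the utility
    loss);
informal care
    attributable case-years times unpaid caregiving hours valued at a
    care-worker hourly wage.

Wages come from a survey-era Mincer fit and are treated as already
expressed in reporting-year currency, so only currency conversion
applies to them; unit treatment costs are inflated from the costing
year first.  Results are reported in millions of 2020 USD by the seven
reporting condition groups, with a secondhand-smoke column added as a
fixed sex-specific uplift of the condition-attributable totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import round_half_up
from .microsim import AGE_MIN, N_AGE, SimulationResult
from .parameters import (
    CONDITION_GROUPS,
    CONDITION_IDS,
    GROUP_ORDER,
    SEXES,
    CountryModel,
    EconomicParams,
)

CATEGORIES = ("direct_medical", "premature_mortality", "disability", "informal_care")


def adjust_inflation(amount: float, factor: float) -> float:
    """Inflate a costing-year amount to the reporting year: amount x (1+factor)."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if factor < 0:
        raise ValueError("inflation factor must be >= 0")
    return amount * (1.0 + factor)


def convert_currency(amount_local: float, rate: float) -> float:
    """Local currency -> USD at ``rate`` local units per USD."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_local / rate


def mincer_wage(age: float, sex: str, education_years: float, econ: EconomicParams) -> float:
    """Annual wage from the log-linear Mincer equation.

    wage = exp(b0 + b_edu * education + b_age * age + b_age2 * age^2),
    with sex-specific coefficients.
    """
    b = econ.mincer[sex]
    return float(
        np.exp(
            b["beta0"]
            + b["beta_edu"] * education_years
            + b["beta_age"] * age
            + b["beta_age2"] * age * age
        )
    )


def pv_future_income(age: float, sex: str, econ: EconomicParams, wage_fn=None) -> float:
    """Present value of labor income from ``age`` to retirement.

    Sum over t = 1..T of wage(age + t) x (1+g)^t / (1+r)^t with
    T = retirement_age - age.  Returns 0 at or beyond retirement.
    ``wage_fn(age, sex)`` defaults to the Mincer wage at the sex's mean
    education.
    """
    retirement = econ.retirement_age[sex]
    T = int(np.floor(retirement - age))
    if T <= 0:
        return 0.0
    if wage_fn is None:
        edu = econ.mean_education_years[sex]
        wage_fn = lambda a, s: mincer_wage(a, s, edu, econ)  # noqa: E731
    r, g = econ.discount_rate, econ.wage_growth_rate
    t = np.arange(1, T + 1)
    wages = np.array([wage_fn(age + ti, sex) for ti in t])
    return float(np.sum(wages * (1 + g) ** t / (1 + r) ** t))


def presenteeism_cost(qol_decrement: float, years_in_state: float, wage: float) -> float:
    """Productivity lost while working ill: wage x decrement x years."""
    if not (0 <= qol_decrement <= 1):
        raise ValueError("quality-of-life decrement outside [0,1]")
    return wage * qol_decrement * years_in_state


def informal_care_cost(hours: float, caregiver_wage: float) -> float:
    """Unpaid caregiving valued at the care-worker wage: hours x wage."""
    if hours < 0 or caregiver_wage < 0:
        raise ValueError("hours and wage must be >= 0")
    return hours * caregiver_wage


@dataclass
class CostResult:
    """Attributable costs in millions of 2020 USD.

    ``cells`` is indexed by reporting group with a (category, sex)
    column MultiIndex.  Conservation holds before rounding: the grand
    total equals both the sum over categories and the sum over groups.
    """

    cells: pd.DataFrame
    gdp_musd: float | None = None

    def category_total(self, category: str) -> float:
        return float(self.cells[category].to_numpy().sum())

    def group_total(self, group: str) -> float:
        return float(self.cells.loc[group].to_numpy().sum())

    @property
    def grand_total(self) -> float:
        return float(self.cells.to_numpy().sum())

    def category_totals(self) -> dict:
        return {c: self.category_total(c) for c in CATEGORIES}


def direct_medical_cost(case_years: float, annual_cost: float, econ: EconomicParams) -> float:
    """USD cost of attributable case-years at a 2015 local-currency unit cost."""
    if annual_cost < 0:
        raise ValueError("unit cost must be >= 0")
    return convert_currency(
        adjust_inflation(case_years * annual_cost, econ.inflation_factor),
        econ.exchange_rate_pen_per_usd,
    )


def compute_costs(
    factual: SimulationResult,
    counterfactual: SimulationResult,
    model: CountryModel,
    years: tuple[int, int] = (0, 1),
    scale: float | None = None,
) -> CostResult:
    """Attributable costs over simulation years ``[start, stop)``.

    Case-years and deaths are factual minus counterfactual, floored at
    0 per (condition, sex, age) cell, scaled to the population.
    """
    if scale is None:
        scale = model.total_population / factual.n
    econ = model.econ
    y0, y1 = years
    fx = econ.exchange_rate_pen_per_usd

    # attributable case-years and deaths by (condition, sex, age)
    d_py = np.clip(
        factual.disease_py[y0:y1].sum(axis=0) - counterfactual.disease_py[y0:y1].sum(axis=0),
        0.0,
        None,
    ) * scale
    d_deaths = np.clip(
        factual.deaths[y0:y1].sum(axis=0) - counterfactual.deaths[y0:y1].sum(axis=0),
        0.0,
        None,
    ) * scale

    ages = np.arange(AGE_MIN, AGE_MIN + N_AGE)
    pv = np.zeros((2, N_AGE))
    wage = np.zeros((2, N_AGE))
    working = np.zeros((2, N_AGE), dtype=bool)
    for s, sex in enumerate(SEXES):
        edu = econ.mean_education_years[sex]
        for i, a in enumerate(ages):
            working[s, i] = 35 <= a < econ.retirement_age[sex]
            if a < econ.retirement_age[sex]:
                pv[s, i] = pv_future_income(a, sex, econ)
            wage[s, i] = mincer_wage(a, sex, edu, econ)

    a35 = 35 - AGE_MIN
    groups = [g for g in GROUP_ORDER if g != "shs_other"]
    cols = pd.MultiIndex.from_product([CATEGORIES, SEXES])
    cells = pd.DataFrame(0.0, index=list(GROUP_ORDER), columns=cols)

    for k, cid in enumerate(CONDITION_IDS):
        d = model.disease(cid)
        g = CONDITION_GROUPS[cid]
        for s, sex in enumerate(SEXES):
            cy = d_py[k, s, a35:].sum()  # case-years at ages 35+
            cells.loc[g, ("direct_medical", sex)] += (
                direct_medical_cost(cy, d.annual_direct_cost, econ) / 1e6
            )
            cells.loc[g, ("informal_care", sex)] += (
                informal_care_cost(cy * d.informal_care_hours_per_year, econ.caregiver_hourly_wage)
                / fx
                / 1e6
            )
            # presenteeism: sum over working ages of case-years x wage x decrement
            wage_years = float((d_py[k, s][working[s]] * wage[s][working[s]]).sum())
            cells.loc[g, ("disability", sex)] += (
                presenteeism_cost(d.disability_weight, 1.0, wage_years) / fx / 1e6
            )
            cells.loc[g, ("premature_mortality", sex)] += (
                (d_deaths[k, s] * pv[s]).sum() / fx / 1e6
            )

    # secondhand smoke and other causes: fixed uplift of the sex totals
    for s, sex in enumerate(SEXES):
        u = model.shs_uplift[sex]
        for cat in CATEGORIES:
            cells.loc["shs_other", (cat, sex)] = u * sum(
                cells.loc[g, (cat, sex)] for g in groups
            )

    return CostResult(cells=cells, gdp_musd=econ.gdp_musd)


def cost_shares(result, gdp_musd: float | None = None) -> dict:
    """Category shares (%) of the grand total, rounded to one decimal.

    ``result`` may be a :class:`CostResult` or a mapping/sequence of the
    four category totals in :data:`CATEGORIES` order.  Adds
    ``gdp_share`` (total as % of GDP) and ``gdp_share_direct`` when a
    GDP is available.  Returns None values when the total is zero.
    """
    if isinstance(result, CostResult):
        totals = result.category_totals()
        gdp_musd = gdp_musd if gdp_musd is not None else result.gdp_musd
    elif isinstance(result, dict):
        totals = {c: float(result[c]) for c in CATEGORIES}
    else:
        vals = list(result)
        totals = dict(zip(CATEGORIES, map(float, vals)))
    grand = sum(totals.values())
    if grand == 0:
        return {c: None for c in CATEGORIES}
    shares = {c: round_half_up(100.0 * v / grand, 1) for c, v in totals.items()}
    if gdp_musd:
        shares["gdp_share"] = round_half_up(100.0 * grand / gdp_musd, 2)
        shares["gdp_share_direct"] = round_half_up(
            100.0 * totals["direct_medical"] / gdp_musd, 2
        )
    return shares


def cost_table(result: CostResult) -> pd.DataFrame:
    """Report-shaped cost table: categories x sex rows, group columns.

    Values in millions of 2020 USD, rounded to one decimal at report
    time only.
    """
    rows = []
    for cat in CATEGORIES:
        for sex in list(SEXES) + ["total"]:
            row = {"category": cat, "sex": sex}
            for g in GROUP_ORDER:
                if sex == "total":
                    v = sum(result.cells.loc[g, (cat, s)] for s in SEXES)
                else:
                    v = result.cells.loc[g, (cat, sex)]
                row[g] = round_half_up(float(v), 1)
            row["total"] = round_half_up(
                float(
                    sum(
                        result.cells.loc[g, (cat, s)]
                        for g in GROUP_ORDER
                        for s in (SEXES if sex == "total" else [sex])
                    )
                ),
                1,
            )
            rows.append(row)
    total_row = {"category": "total", "sex": "total"}
    for g in GROUP_ORDER:
        total_row[g] = round_half_up(result.group_total(g), 1)
    total_row["total"] = round_half_up(result.grand_total, 1)
    rows.append(total_row)
    return pd.DataFrame(rows)
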