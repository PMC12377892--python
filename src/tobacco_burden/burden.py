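"""Attributable burden accounting: deaths, events, YLL/YLD/DALY.

The attributable burden of smoking is the difference between a factual
simulation and a never-smoker counterfactual run under common random
numbers, floored at zero cell-by-cell.  Annual burden tables report the
outcomes of simulation year 0 (the snapshot year) scaled to the
national population; YLL uses period life-table residual expectancy at
the age of death (undiscounted), and YLD values the disability-weighted
person-years lived in each disease state during the year.

A fixed secondhand-smoke / perinatal uplift row (12% of the female and
13.6% of the male attributable totals by default) is added on top of
the condition-specific burden for deaths and DALYs; condition-specific
events get no uplift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microsim import AGE_MIN, SimulationResult
from .parameters import CONDITION_IDS, CONDITION_LABELS, SEXES, CountryModel

SHS_ROW = "shs_other"


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (0.5 -> 1), as printed report cells are."""
    f = 10.0 ** decimals
    return math.floor(abs(x) * f + 0.5) / f * (1 if x >= 0 else -1)


def attributable_fraction(attributable: float, total: float) -> float | None:
    """Percent of a total that is attributable, rounded half-up to 1 decimal.

    Returns None (a not-applicable marker) when the total is zero.
    """
    if total == 0:
        return None
    if not (0 <= attributable <= total):
        raise ValueError(
            f"attributable={attributable} outside [0, total={total}]"
        )
    return round_half_up(100.0 * attributable / total, 1)


def _check_paired(factual: SimulationResult, counterfactual: SimulationResult) -> None:
    if (factual.n, factual.seed) != (counterfactual.n, counterfactual.seed):
        raise ValueError(
            "factual and counterfactual runs must share n and seed "
            "(common-random-numbers contract)"
        )
    if factual.n_years != counterfactual.n_years:
        raise ValueError("runs must share the simulation horizon")


def attributable_counts(
    factual: SimulationResult, counterfactual: SimulationResult, year: int = 0,
    min_age: int = 35,
) -> pd.DataFrame:
    """Per condition x sex: total and attributable deaths and events.

    Totals come from the factual run; attributable = factual minus
    counterfactual, floored at 0.  Counts are raw (per ``n`` simulated);
    callers scale to the population.  Event cells for conditions whose
    event attribution is not computable are set to NaN.
    """
    _check_paired(factual, counterfactual)
    df = factual.deaths_by_condition_sex(year, min_age)
    dc = counterfactual.deaths_by_condition_sex(year, min_age)
    ef = factual.events_by_condition_sex(year, min_age)
    ec = counterfactual.events_by_condition_sex(year, min_age)

    rows = []
    for k, cid in enumerate(CONDITION_IDS):
        for s, sex in enumerate(SEXES):
            rows.append(
                {
                    "condition": cid,
                    "sex": sex,
                    "total_deaths": df[k, s],
                    "att_deaths": max(df[k, s] - dc[k, s], 0.0),
                    "total_events": ef[k, s],
                    "att_events": max(ef[k, s] - ec[k, s], 0.0),
                }
            )
    return pd.DataFrame(rows)


def compute_yll(death_ages: np.ndarray, life_table: pd.DataFrame, sex: str) -> float:
    """Sum of residual life expectancy at each age of death (years).

    ``death_ages`` are exact ages; each is looked up in the life-table
    band that covers it.  Raises when an age falls outside the table.
    """
    sub = life_table[life_table["sex"] == sex]
    total = 0.0
    for a in np.asarray(death_ages, dtype=float):
        row = sub[(sub["age_lo"] <= a) & (a <= sub["age_hi"])]
        if row.empty:
            raise ValueError(f"death age {a} not covered by the life table")
        total += float(row["residual_le"].iloc[0])
    return total


def compute_yld(case_years: float, disability_weight: float) -> float:
    """Years lived with disability: weight x years lived in the state."""
    if not (0 <= disability_weight <= 1):
        raise ValueError("disability weight outside [0,1]")
    return disability_weight * case_years


@dataclass
class BurdenResult:
    """Attributable burden per condition and sex, plus uplift and totals.

    ``table`` has one row per (condition, sex) with unrounded total and
    attributable deaths/events and attributable YLL/YLD/DALY, already
    scaled to the national population.  ``shs`` holds the uplift row
    per sex (deaths, yll, yld, daly); it is empty until
    :func:`apply_shs_uplift` runs.
    """

    table: pd.DataFrame
    scale: float
    shs: dict = field(default_factory=dict)

    def _sum(self, col: str, sex: str | None = None) -> float:
        t = self.table if sex is None else self.table[self.table["sex"] == sex]
        return float(t[col].sum(skipna=True))

    def total_attributable_deaths(self, include_shs: bool = True) -> float:
        base = self._sum("att_deaths")
        if include_shs:
            base += sum(v["deaths"] for v in self.shs.values())
        return base

    def total_attributable_events(self) -> float:
        return self._sum("att_events")

    def total_yll(self, include_shs: bool = True) -> float:
        base = self._sum("att_yll")
        if include_shs:
            base += sum(v["yll"] for v in self.shs.values())
        return base

    def total_yld(self, include_shs: bool = True) -> float:
        base = self._sum("att_yld")
        if include_shs:
            base += sum(v["yld"] for v in self.shs.values())
        return base

    def total_daly(self, include_shs: bool = True) -> float:
        return self.total_yll(include_shs) + self.total_yld(include_shs)


def compute_burden(
    factual: SimulationResult,
    counterfactual: SimulationResult,
    model: CountryModel,
    year: int = 0,
    scale: float | None = None,
) -> BurdenResult:
    """Assemble the attributable burden for one simulation year.

    ``scale`` converts simulated counts to population counts; the
    default is national population / n simulated.
    """
    _check_paired(factual, counterfactual)
    if scale is None:
        scale = model.total_population / factual.n

    counts = attributable_counts(factual, counterfactual, year)
    a0 = 35 - AGE_MIN

    rows = []
    for k, cid in enumerate(CONDITION_IDS):
        d = model.disease(cid)
        for s, sex in enumerate(SEXES):
            c = counts[(counts["condition"] == cid) & (counts["sex"] == sex)].iloc[0]
            yll_f = factual.yll[year, k, s]
            yll_c = counterfactual.yll[year, k, s]
            py_f = factual.disease_py[year, k, s, a0:].sum()
            py_c = counterfactual.disease_py[year, k, s, a0:].sum()
            att_yll = max(yll_f - yll_c, 0.0) * scale
            att_yld = compute_yld(max(py_f - py_c, 0.0) * scale, d.disability_weight)
            rows.append(
                {
                    "condition": cid,
                    "sex": sex,
                    "total_deaths": c["total_deaths"] * scale,
                    "att_deaths": c["att_deaths"] * scale,
                    "total_events": c["total_events"] * scale,
                    "att_events": (
                        c["att_events"] * scale if d.event_af_computable else np.nan
                    ),
                    "att_yll": att_yll,
                    "att_yld": att_yld,
                    "att_daly": att_yll + att_yld,
                }
            )
    result = BurdenResult(table=pd.DataFrame(rows), scale=scale)
    return apply_shs_uplift(result, model.shs_uplift)


def apply_shs_uplift(burden: BurdenResult, uplift: dict) -> BurdenResult:
    """Add the secondhand-smoke/other-causes row: uplift x sex totals.

    Applies to attributable deaths and DALY components only; replaces
    any previously applied uplift.
    """
    for sex, u in uplift.items():
        if u < 0:
            raise ValueError("uplift fractions must be >= 0")
    burden.shs = {}
    for sex, u in uplift.items():
        burden.shs[sex] = {
            "deaths": u * burden._sum("att_deaths", sex),
            "yll": u * burden._sum("att_yll", sex),
            "yld": u * burden._sum("att_yld", sex),
        }
        burden.shs[sex]["daly"] = burden.shs[sex]["yll"] + burden.shs[sex]["yld"]
    return burden


def burden_table(burden: BurdenResult) -> pd.DataFrame:
    """Report-shaped table: one row per condition plus uplift and total rows.

    Counts are rounded half-up to integers and attributable fractions
    to one decimal only here; internal arithmetic stays unrounded.
    """
    t = burden.table
    rows = []

    def fmt(att, tot):
        frac = attributable_fraction(min(att, tot), tot) if tot > 0 else None
        return round_half_up(att), frac

    for cid in CONDITION_IDS:
        sub = t[t["condition"] == cid]
        row = {"condition": CONDITION_LABELS[cid]}
        tot_d = sub["total_deaths"].sum()
        att_d = sub["att_deaths"].sum()
        row["total_deaths"] = round_half_up(tot_d)
        row["att_deaths"], row["att_deaths_pct"] = fmt(att_d, tot_d)
        for sex in SEXES:
            r = sub[sub["sex"] == sex].iloc[0]
            row[f"att_deaths_{sex}"], row[f"att_deaths_pct_{sex}"] = fmt(
                r["att_deaths"], r["total_deaths"]
            )
        if sub["att_events"].isna().all():
            row["total_events"] = round_half_up(sub["total_events"].sum())
            row["att_events"] = None
            row["att_events_pct"] = None
        else:
            tot_e = sub["total_events"].sum()
            att_e = sub["att_events"].sum()
            row["total_events"] = round_half_up(tot_e)
            row["att_events"], row["att_events_pct"] = fmt(att_e, tot_e)
        row["att_yll"] = round_half_up(sub["att_yll"].sum())
        row["att_yld"] = round_half_up(sub["att_yld"].sum())
        row["att_daly"] = round_half_up(sub["att_daly"].sum())
        rows.append(row)

    if burden.shs:
        shs_deaths = sum(v["deaths"] for v in burden.shs.values())
        rows.append(
            {
                "condition": "Exposure to environmental smoke and other causes",
                "total_deaths": round_half_up(shs_deaths),
                "att_deaths": round_half_up(shs_deaths),
                "att_deaths_pct": 100.0,
                **{
                    f"att_deaths_{sex}": round_half_up(burden.shs[sex]["deaths"])
                    for sex in SEXES
                    if sex in burden.shs
                },
                "total_events": None,
                "att_events": None,
                "att_events_pct": None,
                "att_yll": round_half_up(sum(v["yll"] for v in burden.shs.values())),
                "att_yld": round_half_up(sum(v["yld"] for v in burden.shs.values())),
                "att_daly": round_half_up(sum(v["daly"] for v in burden.shs.values())),
            }
        )

    total = {
        "condition": "Total",
        "total_deaths": round_half_up(
            t["total_deaths"].sum() + sum(v["deaths"] for v in burden.shs.values())
        ),
        "att_deaths": round_half_up(burden.total_attributable_deaths()),
        "att_deaths_pct": attributable_fraction(
            min(
                burden.total_attributable_deaths(),
                t["total_deaths"].sum() + sum(v["deaths"] for v in burden.shs.values()),
            ),
            t["total_deaths"].sum() + sum(v["deaths"] for v in burden.shs.values()),
        ),
        "total_events": round_half_up(t["total_events"].sum()),
        "att_events": round_half_up(burden.total_attributable_events()),
        "att_events_pct": attributable_fraction(
            min(burden.total_attributable_events(), t["total_events"].sum()),
            t["total_events"].sum(),
        )
        if t["total_events"].sum() > 0
        else None,
        "att_yll": round_half_up(burden.total_yll()),
        "att_yld": round_half_up(burden.total_yld()),
        "att_daly": round_half_up(burden.total_daly()),
    }
    rows.append(total)
    return pd.DataFrame(rows)
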