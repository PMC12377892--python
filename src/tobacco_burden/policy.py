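"""Tobacco-control policy projections.

A policy lowers smoking prevalence through
``prev_post = prev_pre * (1 - Em * Ip)`` where ``Em`` is the relative
reduction in tobacco consumption the measure achieves and ``Ip`` the
fraction of that reduction expressed as lower smoker prevalence
(default 0.5: about half of a consumption drop comes from quitting,
the other half from lighter smoking among continuing smokers).  For
tax scenarios ``Em`` follows from the price change through the price
elasticity of demand.

A scenario run compares the factual baseline with a run whose moved
smokers are reassigned current -> former (quitting, not history
erasure) under common random numbers, cumulated over a 10-year horizon
in a steady state: population, unit costs, and wages are held fixed,
so only the prevalence change drives the difference.  Smoke-free
scenarios additionally scale the secondhand-smoke burden row by the
assumed nonsmoker risk reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CATEGORIES, compute_costs
from .microsim import AGE_MIN, simulate_population
from .parameters import (
    CONDITION_GROUPS,
    CONDITION_IDS,
    GROUP_ORDER,
    SEXES,
    CountryModel,
)

POLICY_KINDS = ("packaging", "smokefree", "taps_ban", "tax")


def post_policy_prevalence(prev_pre: float, em: float, ip: float) -> float:
    """Prevalence after a policy: prev_pre * (1 - Em * Ip)."""
    for name, v in (("prev_pre", prev_pre), ("em", em), ("ip", ip)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0,1]")
    return prev_pre - em * ip * prev_pre


def tax_effect(price_increase: float, elasticity: float) -> float:
    """Consumption reduction from a price rise: min(1, |elasticity| * rise).

    Constant-elasticity approximation; ``elasticity`` must be <= 0.
    """
    if price_increase < 0:
        raise ValueError("price increase must be >= 0")
    if elasticity > 0:
        raise ValueError("price elasticity of demand must be <= 0")
    return min(1.0, abs(elasticity) * price_increase)


def tax_revenue_change(
    price_increase: float,
    elasticity: float,
    baseline_consumption: float,
    tax_share: float,
    price: float = 1.0,
) -> float:
    """Change in tax receipts when the tax absorbs the price increase.

    Old receipts are ``tax_share * price`` per unit on
    ``baseline_consumption`` units; the new per-unit tax adds the full
    price increase, while demand falls by ``Em``.
    """
    if not (0.0 <= tax_share <= 1.0):
        raise ValueError("tax_share outside [0,1]")
    em = tax_effect(price_increase, elasticity)
    old_tax = tax_share * price
    new_tax = old_tax + price * price_increase
    return new_tax * baseline_consumption * (1.0 - em) - old_tax * baseline_consumption


@dataclass
class PolicyScenario:
    """One intervention.

    For ``kind="tax"`` give ``price_increase`` and ``elasticity``; Em
    is derived.  ``em_range`` (lo, hi) adds uncertainty bounds.  The
    published effectiveness values for packaging/smoke-free/TAPS
    scenarios were never released; the shipped defaults in
    :func:`default_scenarios` are placeholders with wide ranges, not
    published estimates.
    """

    name: str
    kind: str
    em: float | None = None
    em_range: tuple[float, float] | None = None
    ip: float = 0.5
    price_increase: float | None = None
    elasticity: float | None = None
    shs_risk_reduction: float = 0.0
    horizon_years: int = 10

    def __post_init__(self):
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind: {self.kind!r}")
        if self.horizon_years < 1:
            raise ValueError("horizon must be >= 1 year")
        if self.kind == "tax":
            if self.price_increase is None or self.elasticity is None:
                raise ValueError("tax scenarios need price_increase and elasticity")
            self.em = tax_effect(self.price_increase, self.elasticity)
        if self.em is None:
            raise ValueError("scenario needs an effectiveness Em")
        if not (0.0 <= self.em <= 1.0):
            raise ValueError("Em outside [0,1]")
        if not (0.0 <= self.ip <= 1.0):
            raise ValueError("Ip outside [0,1]")


#: default elasticity for tax scenarios; a typical low/middle-income
#: value, NOT a published country estimate — override per analysis.
DEFAULT_ELASTICITY = -0.4


def default_scenarios(elasticity: float = DEFAULT_ELASTICITY) -> list[PolicyScenario]:
    """The four modelled interventions with placeholder effectiveness."""
    return [
        PolicyScenario("plain_packaging", "packaging", em=0.05, em_range=(0.025, 0.125)),
        PolicyScenario(
            "smokefree_enforcement", "smokefree", em=0.04, em_range=(0.017, 0.076),
            shs_risk_reduction=0.2,
        ),
        PolicyScenario("taps_ban", "taps_ban", em=0.07, em_range=(0.039, 0.183)),
        PolicyScenario(
            "tax_50", "tax", price_increase=0.50, elasticity=elasticity
        ),
    ]


@dataclass
class ScenarioResult:
    """Cumulative 10-year base-case and avoided burden for one scenario.

    ``base`` and ``reduction`` map reporting groups to dicts with
    deaths/events/dalys/costs (costs in millions of USD); ``*_lo`` /
    ``*_hi`` hold the Em-range bounds when available.  ``cost_savings``
    decomposes the reduction total by cost category.
    """

    scenario: PolicyScenario
    base: pd.DataFrame
    reduction: pd.DataFrame
    reduction_lo: pd.DataFrame | None = None
    reduction_hi: pd.DataFrame | None = None
    cost_savings: dict = field(default_factory=dict)
    tax_revenue_gain_musd: float | None = None
    n: int = 0
    seed: int = 0

    @property
    def avoided_deaths(self) -> float:
        return float(self.reduction["deaths"].sum())

    @property
    def avoided_events(self) -> float:
        return float(self.reduction["events"].sum())

    @property
    def avoided_dalys(self) -> float:
        return float(self.reduction["dalys"].sum())

    @property
    def cost_savings_musd(self) -> float:
        return float(self.reduction["costs"].sum())


def _group_outcomes(factual, counterfactual, model, scale, horizon, shs_scale=1.0):
    """Attributable outcomes by reporting group, cumulated over the horizon.

    Returns a DataFrame indexed by group with deaths, events, dalys,
    costs columns, plus the per-category cost totals.
    """
    a35 = 35 - AGE_MIN
    y0, y1 = 0, horizon
    d = np.clip(
        factual.deaths[y0:y1, :, :, a35:].sum(axis=(0, 3))
        - counterfactual.deaths[y0:y1, :, :, a35:].sum(axis=(0, 3)),
        0.0,
        None,
    ) * scale
    e = np.clip(
        factual.events[y0:y1, :, :, a35:].sum(axis=(0, 3))
        - counterfactual.events[y0:y1, :, :, a35:].sum(axis=(0, 3)),
        0.0,
        None,
    ) * scale
    yll = np.clip(
        factual.yll[y0:y1].sum(axis=0) - counterfactual.yll[y0:y1].sum(axis=0),
        0.0,
        None,
    ) * scale
    py = np.clip(
        factual.disease_py[y0:y1, :, :, a35:].sum(axis=(0, 3))
        - counterfactual.disease_py[y0:y1, :, :, a35:].sum(axis=(0, 3)),
        0.0,
        None,
    ) * scale

    costs = compute_costs(factual, counterfactual, model, years=(y0, y1), scale=scale)

    groups = {g: {"deaths": 0.0, "events": 0.0, "dalys": 0.0, "costs": 0.0} for g in GROUP_ORDER}
    for k, cid in enumerate(CONDITION_IDS):
        g = CONDITION_GROUPS[cid]
        dw = model.disease(cid).disability_weight
        groups[g]["deaths"] += d[k].sum()
        groups[g]["events"] += e[k].sum()
        groups[g]["dalys"] += yll[k].sum() + dw * py[k].sum()
    for g in GROUP_ORDER:
        if g == "shs_other":
            continue
        groups[g]["costs"] = float(costs.cells.loc[g].sum())

    # secondhand-smoke row: sex-specific uplift of the condition totals
    for s, sex in enumerate(SEXES):
        u = model.shs_uplift[sex] * shs_scale
        groups["shs_other"]["deaths"] += u * d[:-1, s].sum()
        groups["shs_other"]["dalys"] += u * (
            yll[:-1, s].sum()
            + sum(
                model.disease(cid).disability_weight * py[k, s].sum()
                for k, cid in enumerate(CONDITION_IDS)
            )
        )
        groups["shs_other"]["costs"] += (shs_scale) * float(
            costs.cells.loc["shs_other", pd.IndexSlice[:, sex]].sum()
        )
    cat_totals = {
        c: costs.category_total(c)
        - (1.0 - shs_scale)
        * float(costs.cells.loc["shs_other", c].sum())
        for c in CATEGORIES
    }

    df = pd.DataFrame(groups).T.loc[list(GROUP_ORDER)]
    return df, cat_totals


def run_scenario(
    model: CountryModel,
    scenario: PolicyScenario,
    n: int,
    seed: int,
) -> ScenarioResult:
    """Project one scenario: baseline vs post-policy prevalence, common seed.

    The base case is the smoking-attributable burden without the policy
    (factual vs never-smoker counterfactual); the reduction is base
    minus the same quantity under post-policy prevalence, both
    cumulated over the scenario horizon, floored at zero per group.
    """
    horizon = scenario.horizon_years
    scale = model.total_population / n
    shs_scale = 1.0 - scenario.shs_risk_reduction

    factual = simulate_population(model, n, seed, "factual", horizon)
    never = simulate_population(model, n, seed, "never_smoker", horizon)
    base, base_cats = _group_outcomes(factual, never, model, scale, horizon)

    def reduction_for(em: float):
        policy = simulate_population(
            model, n, seed, "factual", horizon, policy_em_ip=em * scenario.ip
        )
        scen, scen_cats = _group_outcomes(
            policy, never, model, scale, horizon, shs_scale=shs_scale
        )
        red = (base - scen).clip(lower=0.0)
        cats = {c: max(base_cats[c] - scen_cats[c], 0.0) for c in CATEGORIES}
        return red, cats

    reduction, cats = reduction_for(scenario.em)
    red_lo = red_hi = None
    if scenario.em_range is not None:
        lo, hi = scenario.em_range
        red_lo, _ = reduction_for(lo)
        red_hi, _ = reduction_for(hi)

    revenue = None
    if scenario.kind == "tax":
        e = model.econ
        revenue = tax_revenue_change(
            scenario.price_increase,
            scenario.elasticity,
            e.baseline_packs_millions,
            e.tax_share,
            e.pack_price,
        ) / e.exchange_rate_pen_per_usd

    return ScenarioResult(
        scenario=scenario,
        base=base,
        reduction=reduction,
        reduction_lo=red_lo,
        reduction_hi=red_hi,
        cost_savings=cats,
        tax_revenue_gain_musd=revenue,
        n=n,
        seed=seed,
    )


def scenario_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Report-shaped table: per scenario and group, base case and reduction
    with lower/upper bounds (equal to the point estimate when no Em
    range was given)."""
    horizons = {r.scenario.horizon_years for r in results}
    if len(horizons) > 1:
        raise ValueError("scenario results must share the projection horizon")
    rows = []
    for r in results:
        lo = r.reduction_lo if r.reduction_lo is not None else r.reduction
        hi = r.reduction_hi if r.reduction_hi is not None else r.reduction
        for g in GROUP_ORDER:
            rows.append(
                {
                    "scenario": r.scenario.name,
                    "group": g,
                    "base_deaths": r.base.loc[g, "deaths"],
                    "base_events": r.base.loc[g, "events"],
                    "base_costs_musd": r.base.loc[g, "costs"],
                    "reduction_deaths": r.reduction.loc[g, "deaths"],
                    "reduction_deaths_lo": lo.loc[g, "deaths"],
                    "reduction_deaths_hi": hi.loc[g, "deaths"],
                    "reduction_events": r.reduction.loc[g, "events"],
                    "reduction_costs_musd": r.reduction.loc[g, "costs"],
                    "reduction_costs_musd_lo": lo.loc[g, "costs"],
                    "reduction_costs_musd_hi": hi.loc[g, "costs"],
                }
            )
        total = {
            "scenario": r.scenario.name,
            "group": "total",
            "base_deaths": r.base["deaths"].sum(),
            "base_events": r.base["events"].sum(),
            "base_costs_musd": r.base["costs"].sum(),
            "reduction_deaths": r.avoided_deaths,
            "reduction_deaths_lo": lo["deaths"].sum(),
            "reduction_deaths_hi": hi["deaths"].sum(),
            "reduction_events": r.avoided_events,
            "reduction_costs_musd": r.cost_savings_musd,
            "reduction_costs_musd_lo": lo["costs"].sum(),
            "reduction_costs_musd_hi": hi["costs"].sum(),
        }
        if r.tax_revenue_gain_musd is not None:
            total["tax_revenue_gain_musd"] = r.tax_revenue_gain_musd
        rows.append(total)
    return pd.DataFrame(rows)
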