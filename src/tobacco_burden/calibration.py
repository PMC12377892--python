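"""Calibration of condition mortality against reference registry tables.

Model-predicted cause- and sex-specific annual deaths are compared with
a reference table; a cell passes when its relative deviation is within
15%.  Failing cells trigger a damped multiplicative adjustment of that
condition-sex slice of the incidence hazard, and the model is
re-simulated.  Incidence is the effective knob for annual cause deaths
in this engine: acute deaths scale with incidence through case
fatality, and chronic deaths scale with disease prevalence, which the
steady-state seeding ties to incidence (prevalence ~ incidence x
sojourn, with sojourn ~ 1/mortality, so scaling the in-state mortality
hazard would largely self-cancel).  Relative risks are never touched,
so the smoking effect is preserved.

Calibration simulates at a fixed seed; because the engine uses common
random numbers, re-simulating the unchanged model reproduces the
reference exactly, and convergence is to the calibration seed's
realisation.  Validate at a different seed to detect overfitting to
Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microsim import simulate_population
from .parameters import CONDITION_IDS, SEXES, CountryModel

TOLERANCE = 0.15  # acceptance threshold on |relative deviation|

#: smallest reference count a cell needs to be calibratable: below
#: 1/TOLERANCE deaths the +-15% band is narrower than one integer death,
#: so no hazard adjustment can land inside it
MIN_REFERENCE_COUNT = 7


def relative_deviation(model_value: float, reference_value: float) -> float | None:
    """(model - reference) / reference; None when the reference is zero."""
    if reference_value == 0:
        return None
    return (model_value - reference_value) / reference_value


@dataclass
class ReferenceMortality:
    """Reference annual deaths per condition and sex."""

    deaths: pd.DataFrame  # condition, sex, deaths
    source: str = "synthetic"

    def cell(self, condition: str, sex: str) -> float:
        sub = self.deaths[
            (self.deaths["condition"] == condition) & (self.deaths["sex"] == sex)
        ]
        return float(sub["deaths"].sum())


def reference_from_simulation(model: CountryModel, n: int, seed: int) -> ReferenceMortality:
    """Build a registry-style reference table by simulating one year."""
    res = simulate_population(model, n, seed, "factual", horizon=1)
    d = res.deaths_by_condition_sex(0)
    rows = [
        {"condition": cid, "sex": sex, "deaths": float(d[k, s])}
        for k, cid in enumerate(CONDITION_IDS)
        for s, sex in enumerate(SEXES)
    ]
    return ReferenceMortality(pd.DataFrame(rows), source=f"simulated(seed={seed},n={n})")


@dataclass
class CalibrationReport:
    """Per-cell outcome of a calibration run."""

    table: pd.DataFrame  # condition, sex, model, reference, deviation, passed
    iterations: int
    converged: bool
    factor_history: list = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        applicable = self.table[self.table["deviation"].notna()]
        return bool((applicable["passed"]).all())


def _cells(
    model: CountryModel,
    reference: ReferenceMortality,
    n: int,
    seed: int,
    min_count: int = MIN_REFERENCE_COUNT,
) -> pd.DataFrame:
    res = simulate_population(model, n, seed, "factual", horizon=1)
    d = res.deaths_by_condition_sex(0)
    rows = []
    for k, cid in enumerate(CONDITION_IDS):
        for s, sex in enumerate(SEXES):
            ref = reference.cell(cid, sex)
            mv = float(d[k, s])
            applicable = ref >= min_count
            dev = relative_deviation(mv, ref) if applicable else None
            rows.append(
                {
                    "condition": cid,
                    "sex": sex,
                    "model": mv,
                    "reference": ref,
                    "deviation": dev,
                    "passed": (abs(dev) <= TOLERANCE) if applicable else True,
                }
            )
    return pd.DataFrame(rows)


def calibrate(
    model: CountryModel,
    reference: ReferenceMortality,
    n: int,
    seed: int,
    max_iter: int = 10,
    damping: float = 0.5,
    min_count: int = MIN_REFERENCE_COUNT,
) -> tuple[CountryModel, CalibrationReport]:
    """Adjust hazards until all applicable reference cells are within 15%.

    Returns the adjusted model and a report; non-convergence is flagged
    in the report, never raised.  Cells whose reference count is zero
    or below ``min_count`` are marked not-applicable and excluded
    (raise ``n`` to make more cells calibratable).
    """
    covered = set(reference.deaths["condition"])
    missing = [c for c in CONDITION_IDS if c not in covered]
    if missing:
        raise ValueError(f"reference does not cover conditions: {missing}")

    work = model.copy()
    history: list[dict] = []

    for it in range(max_iter + 1):
        cells = _cells(work, reference, n, seed, min_count)
        applicable = cells[cells["deviation"].notna()]
        if applicable["passed"].all():
            return work, CalibrationReport(cells, iterations=it, converged=True, factor_history=history)
        if it == max_iter:
            break
        factors = {}
        hz = work.hazards
        for _, r in applicable[~applicable["passed"]].iterrows():
            ratio = r["reference"] / max(r["model"], 0.5)  # guard empty model cells
            factor = 1.0 + damping * (ratio - 1.0)
            factors[(r["condition"], r["sex"])] = factor
            sel = (hz["condition_id"] == r["condition"]) & (hz["sex"] == r["sex"])
            hz.loc[sel, "incidence"] = hz.loc[sel, "incidence"] * factor
        history.append(factors)

    return work, CalibrationReport(cells, iterations=max_iter, converged=False, factor_history=history)
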