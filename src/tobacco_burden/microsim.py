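"""First-order Monte-Carlo Markov engine.

Each simulated individual carries a sex, an exact age, a smoking state
(never/current/former), and a set of chronic disease states, and is
advanced in annual cycles until death or the requested horizon.  Within
a cycle the event order is fixed: smoking-state transition, then
per-condition disease events (acute events can kill through case
fatality), then in-state chronic-disease mortality, then background
(other-cause) mortality.

The engine is vectorised over individuals but draws its uniform
variates in a fixed, state-independent layout: one matrix of shape
``(n, 3K + 2)`` per cycle regardless of who is alive.  Because the
draw sequence never depends on simulated state, a factual run and a
never-smoker counterfactual run with the same seed consume identical
random numbers (common random numbers), so their difference isolates
the smoking effect and, with all relative risks >= 1, the factual run
pathwise dominates the counterfactual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import CONDITION_IDS, SEXES, CountryModel

AGE_MIN = 15
AGE_MAX = 109  # individuals still alive at AGE_MAX die at the end of that cycle
N_AGE = AGE_MAX - AGE_MIN + 1

#: smoking-state codes
NEVER, CURRENT, FORMER = 0, 1, 2
STATE_NAMES = {"never": NEVER, "current": CURRENT, "former": FORMER}

#: maximum sojourn (years) assumed when converting chronic incidence to
#: baseline disease prevalence
_MAX_SOJOURN = 25.0


def _expand_bands(df: pd.DataFrame, value_col: str) -> np.ndarray:
    """Band-level table -> dense (2, N_AGE) array indexed by [sex, age-AGE_MIN]."""
    out = np.zeros((2, N_AGE))
    for _, r in df.iterrows():
        s = SEXES.index(r["sex"])
        lo = max(int(r["age_lo"]), AGE_MIN)
        hi = min(int(r["age_hi"]), AGE_MAX)
        if hi >= lo:
            out[s, lo - AGE_MIN : hi - AGE_MIN + 1] = r[value_col]
    return out


class _Lookups:
    """Dense per-age arrays precomputed from a CountryModel."""

    def __init__(self, model: CountryModel):
        self.conditions = [model.disease(cid) for cid in CONDITION_IDS]
        K = len(self.conditions)
        self.K = K

        # population sampling weights per (sex, age): population spread
        # uniformly over the ages of its band
        w = np.zeros((2, N_AGE))
        for _, r in model.strata.iterrows():
            s = SEXES.index(r["sex"])
            lo = max(int(r["age_lo"]), AGE_MIN)
            hi = min(int(r["age_hi"]), AGE_MAX)
            width = hi - lo + 1
            if width > 0:
                w[s, lo - AGE_MIN : hi - AGE_MIN + 1] += r["population"] / width
        self.pop_weights = w / w.sum()

        self.prev_current = _expand_bands(model.smoking.table, "prev_current")
        self.prev_former = _expand_bands(model.smoking.table, "prev_former")

        self.inc = np.zeros((K, 2, N_AGE))
        self.mort = np.zeros((K, 2, N_AGE))
        hz = model.hazards
        for k, d in enumerate(self.conditions):
            sub = hz[hz["condition_id"] == d.condition_id]
            self.inc[k] = _expand_bands(sub, "incidence")
            self.mort[k] = _expand_bands(sub, "mortality")

        self.bg = _expand_bands(model.life_table, "hazard")
        self.res_le = _expand_bands(model.life_table, "residual_le")

        self.rr_current = np.array([d.rr_current for d in self.conditions])
        self.rr_former = np.array([d.rr_former for d in self.conditions])
        self.case_fatality = np.array([d.case_fatality for d in self.conditions])
        self.duration = np.array([d.mean_duration_years for d in self.conditions])
        self.acute = np.array([d.acute for d in self.conditions])
        self.dw = np.array([d.disability_weight for d in self.conditions])

        # mean chronic sojourn from population-average in-state mortality,
        # used to seed baseline chronic prevalence
        self.sojourn = np.zeros(K)
        popw = self.pop_weights
        for k, d in enumerate(self.conditions):
            if not d.acute:
                mbar = float((self.mort[k] * popw).sum() / max(popw.sum(), 1e-12))
                self.sojourn[k] = min(1.0 / max(mbar, 1.0 / _MAX_SOJOURN), _MAX_SOJOURN)


@dataclass
class SimulationResult:
    """Aggregated output of one microsimulation run.

    Array axes: ``year`` is the simulation cycle (0 = the snapshot
    year), ``cause``/``condition`` index :data:`CONDITION_IDS` with an
    extra final cause slot for background mortality, ``sex`` indexes
    (male, female), and ``age`` is exact age minus :data:`AGE_MIN`.
    """

    deaths: np.ndarray        # (T, K+1, 2, N_AGE)
    events: np.ndarray        # (T, K, 2, N_AGE)
    disease_py: np.ndarray    # (T, K, 2, N_AGE) person-years in disease state
    yll: np.ndarray           # (T, K+1, 2) residual life expectancy at death
    person_years: np.ndarray  # (2, N_AGE, 3) by sex, age, smoking state
    base_sex: np.ndarray      # (n,)
    base_age: np.ndarray      # (n,)
    base_state: np.ndarray    # (n,)
    age_at_death: np.ndarray  # (n,) -1 while alive at end of horizon
    n: int
    seed: int
    mode: str
    horizon: int | str

    @property
    def n_years(self) -> int:
        return self.deaths.shape[0]

    @property
    def total_person_years(self) -> float:
        return float(self.person_years.sum())

    def deaths_by_condition_sex(self, year: int = 0, min_age: int = 35) -> np.ndarray:
        """(K+1, 2) death counts in one simulation year, ages >= min_age."""
        a0 = min_age - AGE_MIN
        return self.deaths[year, :, :, a0:].sum(axis=2)

    def events_by_condition_sex(self, year: int = 0, min_age: int = 35) -> np.ndarray:
        a0 = min_age - AGE_MIN
        return self.events[year, :, :, a0:].sum(axis=2)


def simulate_population(
    model: CountryModel,
    n: int,
    seed: int,
    smoking_mode: str = "factual",
    horizon: int | str = "lifetime",
    policy_em_ip: float = 0.0,
) -> SimulationResult:
    """Simulate ``n`` individuals sampled from the model's population.

    ``smoking_mode`` is ``"factual"`` (states sampled from the smoking
    profile) or ``"never_smoker"`` (everyone forced to never-smoker,
    same random streams).  ``horizon`` is a number of annual cycles or
    ``"lifetime"``.  ``policy_em_ip`` (= Em * Ip) moves that fraction
    of baseline current smokers to former at entry, which is how policy
    scenarios lower prevalence.

    Identical ``(model, n, seed, mode, policy_em_ip)`` give bit-identical
    results.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if smoking_mode not in ("factual", "never_smoker"):
        raise ValueError(f"unknown smoking_mode: {smoking_mode!r}")
    if horizon != "lifetime" and (not isinstance(horizon, int) or horizon < 1):
        raise ValueError("horizon must be 'lifetime' or a positive integer")

    lk = _Lookups(model)
    K = lk.K
    rng = np.random.default_rng(seed)

    # --- entry sampling (draw order fixed and state-independent) ---
    u_strat = rng.random(n)
    u_state = rng.random(n)
    u_mover = rng.random(n)
    u_chronic = rng.random((n, K))

    flat_w = lk.pop_weights.reshape(-1)
    idx = np.searchsorted(np.cumsum(flat_w), u_strat, side="right")
    idx = np.minimum(idx, flat_w.size - 1)
    sex = (idx // N_AGE).astype(np.int64)
    age = (idx % N_AGE).astype(np.int64) + AGE_MIN

    factual = smoking_mode == "factual"
    state = np.full(n, NEVER, dtype=np.int64)
    if factual:
        pc = lk.prev_current[sex, age - AGE_MIN]
        pf = lk.prev_former[sex, age - AGE_MIN]
        state[u_state < pc] = CURRENT
        state[(u_state >= pc) & (u_state < pc + pf)] = FORMER
        if policy_em_ip > 0:
            movers = (state == CURRENT) & (u_mover < policy_em_ip)
            state[movers] = FORMER

    base_sex, base_age, base_state = sex.copy(), age.copy(), state.copy()

    def rr_matrix(st: np.ndarray) -> np.ndarray:
        """(n, K) relative-risk multiplier for each individual/condition."""
        rr = np.ones((st.size, K))
        rr[st == CURRENT] = lk.rr_current
        rr[st == FORMER] = lk.rr_former
        return rr

    # baseline chronic-disease prevalence: steady-state approximation
    # prevalence = 1 - exp(-incidence * RR * mean sojourn)
    in_state = np.zeros((n, K), dtype=bool)
    rr0 = rr_matrix(state)
    for k in range(K):
        if lk.acute[k]:
            continue
        h = lk.inc[k, sex, age - AGE_MIN] * rr0[:, k]
        p0 = -np.expm1(-h * lk.sojourn[k])
        in_state[:, k] = u_chronic[:, k] < p0

    T = (AGE_MAX - int(age.min()) + 1) if horizon == "lifetime" else int(horizon)

    deaths = np.zeros((T, K + 1, 2, N_AGE))
    events = np.zeros((T, K, 2, N_AGE))
    disease_py = np.zeros((T, K, 2, N_AGE))
    yll = np.zeros((T, K + 1, 2))
    person_years = np.zeros((2, N_AGE, 3))
    age_at_death = np.full(n, -1, dtype=np.int64)

    alive = np.ones(n, dtype=bool)
    C = 3 * K + 2  # columns: smoking | events | case fatality | chronic mort | bg

    def _acc(arr_slice, mask, s, a, weight=1.0):
        if mask.any():
            np.add.at(arr_slice, (s[mask], a[mask] - AGE_MIN), weight)

    for y in range(T):
        U = rng.random((n, C))
        if not alive.any():
            continue  # keep consuming draws so horizons stay stream-aligned

        ai = age - AGE_MIN
        # person-years: everyone alive at the start of the cycle lives it
        np.add.at(person_years, (sex[alive], ai[alive], state[alive]), 1.0)

        # 1. smoking transitions
        if factual:
            quit_now = alive & (state == CURRENT) & (U[:, 0] < model.smoking.cessation_prob)
            start_now = (
                alive
                & (state == NEVER)
                & (age < 35)
                & (U[:, 0] < model.smoking.initiation_prob)
            )
            state[quit_now] = FORMER
            state[start_now] = CURRENT

        rr = rr_matrix(state)
        dead_now = np.zeros(n, dtype=bool)
        cause = np.full(n, -1, dtype=np.int64)

        # 2. disease events (condition order fixed)
        for k in range(K):
            h = lk.inc[k, sex, ai] * rr[:, k]
            p = -np.expm1(-h)
            hit = alive & (U[:, 1 + k] < p)
            if lk.acute[k]:
                _acc(events[y, k], hit, sex, age)
                _acc(disease_py[y, k], hit, sex, age, lk.duration[k])
                fatal = hit & ~dead_now & (U[:, 1 + K + k] < lk.case_fatality[k])
                cause[fatal] = k
                dead_now |= fatal
            else:
                onset = hit & ~in_state[:, k]
                _acc(events[y, k], onset, sex, age)
                in_state[:, k] |= onset

        # 3. chronic in-state occupancy and mortality
        for k in range(K):
            if lk.acute[k]:
                continue
            occ = alive & in_state[:, k]
            _acc(disease_py[y, k], occ, sex, age)
            pm = -np.expm1(-lk.mort[k, sex, ai])
            fatal = occ & ~dead_now & (U[:, 1 + 2 * K + k] < pm)
            cause[fatal] = k
            dead_now |= fatal

        # 4. background (other-cause) mortality
        p_bg = -np.expm1(-lk.bg[sex, ai])
        fatal = alive & ~dead_now & (U[:, 3 * K + 1] < p_bg)
        cause[fatal] = K
        dead_now |= fatal

        # close the cycle: record deaths, advance survivors
        died = alive & dead_now
        if died.any():
            np.add.at(deaths[y], (cause[died], sex[died], ai[died]), 1.0)
            np.add.at(yll[y], (cause[died], sex[died]), lk.res_le[sex[died], ai[died]])
            age_at_death[died] = age[died]
            alive[died] = False

        age[alive] += 1
        # anyone reaching the age cap dies of background causes
        over = alive & (age > AGE_MAX)
        if over.any():
            np.add.at(deaths[y], (np.full(over.sum(), K), sex[over], np.full(over.sum(), N_AGE - 1)), 1.0)
            age_at_death[over] = AGE_MAX
            alive[over] = False
            age[over] = AGE_MAX

    return SimulationResult(
        deaths=deaths,
        events=events,
        disease_py=disease_py,
        yll=yll,
        person_years=person_years,
        base_sex=base_sex,
        base_age=base_age,
        base_state=base_state,
        age_at_death=age_at_death,
        n=n,
        seed=seed,
        mode=smoking_mode,
        horizon=horizon,
    )


def life_expectancy(
    result: SimulationResult,
    sex: str | None = None,
    smoking_state: str | None = None,
    min_entry_age: int = 35,
) -> float:
    """Mean age at death for a baseline group, among entrants aged >= 35.

    Requires a lifetime-horizon result (everyone dead).  Grouping uses
    the smoking state at entry, so "current" means people who were
    smokers when simulation began regardless of later quitting.
    """
    if result.horizon != "lifetime":
        raise ValueError("life expectancy requires a lifetime-horizon result")
    mask = result.base_age >= min_entry_age
    if sex is not None:
        mask &= result.base_sex == SEXES.index(sex)
    if smoking_state is not None:
        mask &= result.base_state == STATE_NAMES[smoking_state]
    mask &= result.age_at_death >= 0
    if not mask.any():
        raise ValueError("empty group for life expectancy")
    return float(result.age_at_death[mask].mean())
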