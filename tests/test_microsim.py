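import numpy as np
import pytest

from tobacco_burden.microsim import (
    AGE_MIN,
    SimulationResult,
    life_expectancy,
    simulate_population,
)
from tobacco_burden.parameters import CONDITION_IDS

from conftest import make_toy_model

AMI = CONDITION_IDS.index("ami")


class TestEngineBasics:
    def test_zero_hazards_only_aging(self):
        m = make_toy_model(incidence=0.0, background=0.0)
        res = simulate_population(m, 500, seed=3, horizon=5)
        assert res.deaths.sum() == 0
        assert res.events.sum() == 0
        assert res.total_person_years == 500 * 5

    def test_forced_event_and_death(self):
        # hazard so large the event probability is ~1, certain case fatality
        m = make_toy_model(incidence=50.0, case_fatality=1.0, background=0.0)
        res = simulate_population(m, 200, seed=3, horizon=1)
        assert res.events[0, AMI].sum() == 200
        assert res.deaths[0, AMI].sum() == 200

    def test_invalid_inputs_raise(self):
        m = make_toy_model()
        with pytest.raises(ValueError):
            simulate_population(m, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_population(m, 10, seed=1, smoking_mode="sometimes")
        with pytest.raises(ValueError):
            simulate_population(m, 10, seed=1, horizon=0)

    def test_reproducibility_bit_identical(self, peru_model):
        a = simulate_population(peru_model, 2000, seed=11, horizon=3)
        b = simulate_population(peru_model, 2000, seed=11, horizon=3)
        for f in ("deaths", "events", "disease_py", "yll", "person_years"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_person_year_conservation(self, peru_model):
        res = simulate_population(peru_model, 3000, seed=5, horizon=4)
        # each individual contributes one person-year per cycle lived
        died = res.age_at_death >= 0
        years_lived = np.where(
            died, res.age_at_death - res.base_age + 1, 4
        ).sum()
        assert res.total_person_years == years_lived


class TestSmokingEffect:
    def test_rr_one_removes_smoking_effect(self):
        m = make_toy_model(incidence=0.05, case_fatality=0.3,
                           rr_current=1.0, rr_former=1.0)
        f = simulate_population(m, 20_000, seed=9, horizon=3)
        c = simulate_population(m, 20_000, seed=9, smoking_mode="never_smoker", horizon=3)
        np.testing.assert_array_equal(f.deaths, c.deaths)
        np.testing.assert_array_equal(f.events, c.events)

    def test_crn_dominance_total_deaths(self, paired_lifetime):
        factual, never = paired_lifetime
        # with all RRs >= 1 the factual run pathwise dominates
        f = factual.deaths[:, :-1].sum()
        c = never.deaths[:, :-1].sum()
        assert f >= c

    def test_hazard_to_probability_identity(self):
        # all-current-smoker cohort, rr=2: event prob ~ 1 - exp(-2h)
        h = 0.05
        m = make_toy_model(incidence=h, rr_current=2.0, prev_current=1.0,
                           prev_former=0.0, background=0.0)
        n = 100_000
        res = simulate_population(m, n, seed=13, horizon=1)
        p_hat = res.events[0, AMI].sum() / n
        p = -np.expm1(-2 * h)
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestMarkovOracle:
    def test_deaths_match_transition_matrix(self):
        """Monte-Carlo deaths equal the deterministic two-state chain
        propagation within 3 binomial standard errors at n=50,000."""
        h, cf, mu = 0.04, 0.5, 0.02
        prevs, rrs = (0.6, 0.3, 0.1), (1.0, 2.0, 1.5)  # never/current/former
        m = make_toy_model(incidence=h, case_fatality=cf, background=mu,
                           prev_current=prevs[1], prev_former=prevs[2],
                           rr_current=rrs[1], rr_former=rrs[2])
        n, T = 50_000, 8
        res = simulate_population(m, n, seed=17, horizon=T)

        # matrix-vector propagation per smoking state, then mix
        p_dead = 0.0
        for w, rr in zip(prevs, rrs):
            pe = -np.expm1(-h * rr)
            pd = pe * cf + (1 - pe * cf) * (-np.expm1(-mu))
            state = np.array([1.0, 0.0])
            M = np.array([[1 - pd, 0.0], [pd, 1.0]])
            for _ in range(T):
                state = M @ state
            p_dead += w * state[1]

        expected = n * p_dead
        se = np.sqrt(n * p_dead * (1 - p_dead))
        assert abs(res.deaths.sum() - expected) < 3 * se

    def test_events_match_survival_weighted_rate(self):
        h, cf, mu = 0.04, 0.5, 0.02
        m = make_toy_model(incidence=h, case_fatality=cf, background=mu,
                           prev_current=0.0, prev_former=0.0)
        n, T = 50_000, 8
        res = simulate_population(m, n, seed=19, horizon=T)
        pe = -np.expm1(-h)
        pd = pe * cf + (1 - pe * cf) * (-np.expm1(-mu))
        surv = (1 - pd) ** np.arange(T)
        expected = n * pe * surv.sum()
        se = np.sqrt(expected)  # ~Poisson
        assert abs(res.events.sum() - expected) < 3 * se


class TestLifeExpectancy:
    def test_exponential_lifetime_closed_form(self):
        # constant all-cause hazard, no diseases: geometric cycles to death
        mu = 0.2
        m = make_toy_model(incidence=0.0, background=mu)
        res = simulate_population(m, 20_000, seed=23, horizon="lifetime")
        p = -np.expm1(-mu)
        expected = 39.5 + (1 - p) / p  # mean entry age + mean extra cycles
        assert abs(life_expectancy(res) - expected) < 0.15

    def test_rr_one_equalises_groups(self):
        m = make_toy_model(incidence=0.05, case_fatality=0.5, background=0.1,
                           rr_current=1.0, rr_former=1.0)
        res = simulate_population(m, 30_000, seed=29, horizon="lifetime")
        le_s = life_expectancy(res, smoking_state="current")
        le_n = life_expectancy(res, smoking_state="never")
        assert abs(le_s - le_n) < 0.4

    def test_smoker_ordering_on_fixture(self, paired_lifetime):
        factual, _ = paired_lifetime
        le_cur = life_expectancy(factual, smoking_state="current")
        le_fmr = life_expectancy(factual, smoking_state="former")
        le_nev = life_expectancy(factual, smoking_state="never")
        assert le_cur < le_fmr < le_nev

    def test_empty_group_raises(self):
        m = make_toy_model(background=0.5, prev_current=0.0, prev_former=0.0)
        res = simulate_population(m, 1000, seed=1, horizon="lifetime")
        with pytest.raises(ValueError, match="empty group"):
            life_expectancy(res, smoking_state="current")
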