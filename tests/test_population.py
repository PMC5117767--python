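"""Individual-based rhino population model."""

import numpy as np
import pytest

from rhinosim.params import PopulationParams
from rhinosim.population import (
    ALIVE,
    DEAD_NATURAL,
    KNP,
    abundance,
    init_population,
    truncated_age_distribution,
    weekly_step,
)

PARAMS = PopulationParams()
ABUNDANT_AV = 500.0  # well above the mean availability of 160 g/m^2


def test_initial_ages_respect_truncation_bounds():
    state = init_population(1000, 0, PARAMS, seed=0)
    assert state.age.min() >= 1
    assert state.age.max() <= PARAMS.le_weeks


def test_initial_mean_age_matches_truncated_normal():
    """Sample mean age agrees with the closed-form truncated-Gaussian mean."""
    expected = truncated_age_distribution(PARAMS).mean()
    ages = np.concatenate(
        [init_population(10_000, 0, PARAMS, seed=s).age for s in range(3)]
    )
    assert ages.mean() == pytest.approx(expected, rel=0.02)


def test_empty_population():
    state = init_population(0, 0, PARAMS, seed=0)
    assert abundance(state)["total"] == 0
    weekly_step(state, ABUNDANT_AV, 5, PARAMS, np.random.default_rng(0))
    assert state.last_counts.shortfall == 5


def test_negative_initial_count_rejected():
    with pytest.raises(ValueError):
        init_population(-1, 0, PARAMS, seed=0)


def test_abundance_counts_by_subregion():
    state = init_population(300, 200, PARAMS, seed=0)
    ab = abundance(state)
    assert ab == {"knp": 300, "private": 200, "total": 500}


def test_weekly_conservation_identity():
    """N_{t+1} = N_t + births - natural deaths - poached, every week."""
    state = init_population(800, 300, PARAMS, seed=3)
    rng = np.random.default_rng(3)
    n = abundance(state)["total"]
    for week in range(200):
        m = int(rng.integers(0, 6))
        weekly_step(state, 170.0, (m, 0), PARAMS, rng)
        c = state.last_counts
        n_new = abundance(state)["total"]
        assert n_new == n + c.births - c.natural_deaths - c.poached
        n = n_new
        alive = state.alive_mask()
        assert state.age[alive].max(initial=0) <= PARAMS.le_weeks
        assert state.eb[alive].min(initial=0.0) >= 0.0
        assert state.eb[alive].max(initial=0.0) <= PARAMS.meb


def test_no_vegetation_starves_everyone_within_budget():
    """av = 0 for meb consecutive weeks exhausts every energetic budget."""
    state = init_population(500, 100, PARAMS, seed=1)
    rng = np.random.default_rng(1)
    for _ in range(int(PARAMS.meb)):
        weekly_step(state, 0.0, 0, PARAMS, rng)
    assert abundance(state)["total"] == 0
    assert (state.status[: state.n] != ALIVE).all() or state.n == 0


def test_poaching_capped_by_available_matures():
    state = init_population(10, 0, PARAMS, seed=2)
    # force exactly 3 matures, the rest juveniles
    state.age_[: state.n] = PARAMS.ma_weeks - 10
    state.age_[:3] = PARAMS.ma_weeks + 52
    weekly_step(state, ABUNDANT_AV, (5, 0), PARAMS, np.random.default_rng(0))
    c = state.last_counts
    assert c.poached == 3
    assert c.shortfall == 2
    assert (state.status[:3] == 2).all()


def test_zero_order_no_sources_or_sinks():
    state = init_population(200, 0, PARAMS, seed=4)
    # nobody near life expectancy, nobody eligible to calve
    state.age_[: state.n] = np.minimum(state.age, PARAMS.le_weeks - 520)
    state.wsc_[: state.n] = 0
    before = abundance(state)["total"]
    weekly_step(state, ABUNDANT_AV, 0, PARAMS, np.random.default_rng(0))
    c = state.last_counts
    assert c.births == 0 and c.poached == 0
    assert abundance(state)["total"] == before - c.natural_deaths


def test_births_respect_intercalving_interval():
    """A single female's calving events are separated by >= intercalv."""
    params = PopulationParams(base_weekly_mortality=0.0, dens_mortality_coef=0.0)
    state = init_population(2, 0, params, seed=0)
    state.age_[:2] = params.ma_weeks + 104
    state.sex_[0] = True     # the mother
    state.sex_[1] = False    # her mate
    state.wsc_[:2] = params.intercalv_weeks  # eligible immediately
    rng = np.random.default_rng(7)
    birth_weeks = []
    for week in range(200):  # below 208 so no daughter matures
        weekly_step(state, ABUNDANT_AV, 0, params, rng)
        if state.last_counts.births:
            assert state.last_counts.births == 1
            birth_weeks.append(week)
    gaps = np.diff(birth_weeks)
    assert (gaps >= params.intercalv_weeks).all()


def test_identical_seed_identical_trajectory():
    def trajectory(seed):
        state = init_population(400, 150, PARAMS, seed=seed)
        rng = np.random.default_rng(seed + 1)
        totals = []
        for _ in range(100):
            weekly_step(state, 170.0, (2, 1), PARAMS, rng)
            totals.append(abundance(state)["total"])
        return totals

    assert trajectory(11) == trajectory(11)
    assert trajectory(11) != trajectory(12)  # and seeds actually matter


def test_population_sustainable_without_poaching():
    """With m = 0 every week, 35-year abundance does not decline."""
    from rhinosim import engine
    from rhinosim.params import PolicyScenario

    scen = PolicyScenario("no_poaching", p_a=1.0, p_m=0.0, t=0, disruption=False)
    r = engine.run(scen, horizon_years=35, seed=5)
    start = r.trajectory["abundance_total"].iloc[0]
    assert r.final_abundance >= start
    assert r.trajectory["poached"].sum() == 0


def test_demographic_rates_in_recorded_bands_at_high_density():
    """An undisturbed 2014-density population realizes ~7-8.5%/yr births
    and ~1-2%/yr natural mortality, the recorded Kruger rates."""
    from rhinosim import engine
    from rhinosim.params import PolicyScenario

    scen = PolicyScenario("no_poaching", p_a=1.0, p_m=0.0, t=0, disruption=False)
    r = engine.run(scen, horizon_years=2, seed=1)
    n0 = r.trajectory["abundance_total"].iloc[0]
    births = r.trajectory["births"].sum() / 2.0
    deaths = r.trajectory["natural_deaths"].sum() / 2.0
    assert 0.07 <= births / n0 <= 0.085
    assert 0.01 <= deaths / n0 <= 0.02
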