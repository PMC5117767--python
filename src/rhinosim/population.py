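"""Individual-based model of the South African white-rhino meta-population.

Each rhino carries an age, sex, energetic budget (weeks of reserve, after the
prairie-vole formulation), a patch location within one of two sub-regions
(Kruger National Park and private ranches, four enclosed patches each), a
weeks-since-calving clock (females) and a status.  The weekly step applies,
in order: ageing, vegetation-driven energetics, old-age and natural death,
density- and vegetation-dependent calving, and the random removal of ``m``
mature animals by poaching.

The population is held as a structure of numpy arrays so that runs with tens
of thousands of individuals over a 35-year horizon stay cheap; dead rows are
compacted away lazily.  All stochasticity flows through one
``numpy.random.Generator``.

Demographic calibration (the weekly calving probability ``b0``, the logistic
density response, and the density-dependent mortality ramp) reproduces the
region's quantitative anchors: roughly 7-8.5%/yr births and 1-2%/yr natural
mortality at 2012-era Kruger densities, and ~10%/yr realized growth at the
low densities of the late 1990s.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import PopulationParams

__all__ = [
    "ALIVE",
    "DEAD_NATURAL",
    "DEAD_POACHED",
    "KNP",
    "PRIVATE",
    "PopulationState",
    "StepCounts",
    "init_population",
    "weekly_step",
    "abundance",
]

ALIVE, DEAD_NATURAL, DEAD_POACHED = 0, 1, 2
KNP, PRIVATE = 0, 1
_WEANING_WEEKS = 104  # a calf orphaned before this age does not survive
_SUBREGION_NAMES = {KNP: "knp", PRIVATE: "private"}


@dataclass
class StepCounts:
    """Demographic bookkeeping for one weekly step."""

    births: int = 0
    natural_deaths: int = 0
    poached: int = 0
    shortfall: int = 0  # poach orders that found no mature rhino to fill


class PopulationState:
    """Structure-of-arrays container for the rhino population.

    Attributes ending in an underscore are the backing arrays sized to
    ``capacity``; only the first ``n`` slots are meaningful.  Dead rows are
    retained until :meth:`compact` removes them, so ``abundance`` always
    counts ``status == ALIVE`` explicitly.
    """

    __slots__ = (
        "id_", "age_", "sex_", "eb_", "gpatch_", "status_", "wsc_",
        "n", "week", "cumulative_poached", "next_id", "last_counts", "params",
    )

    def __init__(self, params: PopulationParams, capacity: int = 1024):
        self.params = params
        self.id_ = np.zeros(capacity, dtype=np.int64)
        self.age_ = np.zeros(capacity, dtype=np.int32)       # weeks
        self.sex_ = np.zeros(capacity, dtype=bool)           # True = female
        self.eb_ = np.zeros(capacity, dtype=np.float32)      # weeks of reserve
        self.gpatch_ = np.zeros(capacity, dtype=np.int8)     # subregion*4 + patch
        self.status_ = np.zeros(capacity, dtype=np.int8)
        self.wsc_ = np.zeros(capacity, dtype=np.int32)       # weeks since calving
        self.n = 0
        self.week = 0
        self.cumulative_poached = 0
        self.next_id = 0
        self.last_counts = StepCounts()

    # -- array views over the used slots --------------------------------
    @property
    def age(self):
        return self.age_[: self.n]

    @property
    def sex_female(self):
        return self.sex_[: self.n]

    @property
    def eb(self):
        return self.eb_[: self.n]

    @property
    def gpatch(self):
        return self.gpatch_[: self.n]

    @property
    def subregion(self):
        return self.gpatch_[: self.n] // self.params.patches_per_subregion

    @property
    def status(self):
        return self.status_[: self.n]

    @property
    def weeks_since_calving(self):
        return self.wsc_[: self.n]

    @property
    def ids(self):
        return self.id_[: self.n]

    def alive_mask(self) -> np.ndarray:
        return self.status_[: self.n] == ALIVE

    # -- storage management --------------------------------------------
    def _grow(self, extra: int) -> None:
        need = self.n + extra
        cap = len(self.status_)
        if need <= cap:
            return
        new_cap = max(need, int(cap * 1.6) + 1024)
        for name in ("id_", "age_", "sex_", "eb_", "gpatch_", "status_", "wsc_"):
            old = getattr(self, name)
            arr = np.zeros(new_cap, dtype=old.dtype)
            arr[: self.n] = old[: self.n]
            setattr(self, name, arr)

    def append(self, *, age, sex_female, eb, gpatch, wsc) -> None:
        """Append new individuals (arrays of equal length) as alive rows."""
        k = len(age)
        if k == 0:
            return
        self._grow(k)
        sl = slice(self.n, self.n + k)
        self.id_[sl] = np.arange(self.next_id, self.next_id + k)
        self.age_[sl] = age
        self.sex_[sl] = sex_female
        self.eb_[sl] = eb
        self.gpatch_[sl] = gpatch
        self.status_[sl] = ALIVE
        self.wsc_[sl] = wsc
        self.n += k
        self.next_id += k

    def compact(self) -> None:
        """Drop dead rows (aggregate counters are unaffected)."""
        keep = self.status_[: self.n] == ALIVE
        k = int(keep.sum())
        for name in ("id_", "age_", "sex_", "eb_", "gpatch_", "status_", "wsc_"):
            arr = getattr(self, name)
            arr[:k] = arr[: self.n][keep]
        self.n = k

    def maybe_compact(self, dead_fraction: float = 0.25) -> None:
        if self.n > 2048:
            dead = self.n - int((self.status_[: self.n] == ALIVE).sum())
            if dead > dead_fraction * self.n:
                self.compact()


def _patch_capacities(params: PopulationParams) -> np.ndarray:
    ppr = params.patches_per_subregion
    return np.concatenate(
        [
            np.full(ppr, params.patch_capacity_knp),
            np.full(ppr, params.patch_capacity_private),
        ]
    )


def truncated_age_distribution(params: PopulationParams) -> stats.rv_continuous:
    """The initial age law: Gaussian(7.5 y, 3 y) truncated to [1 wk, le]."""
    lo, hi = 1.0, params.le * 52.0
    mu, sd = params.init_age_mean * 52.0, params.init_age_sd * 52.0
    return stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


def init_population(
    n0_knp: int,
    n0_private: int,
    params: PopulationParams = PopulationParams(),
    seed: int | np.random.Generator = 0,
) -> PopulationState:
    """Create an initial population.

    Ages are drawn from the truncated Gaussian age law; individuals are
    spread uniformly over each sub-region's four patches; energetic budgets
    start at ``meaneb`` for adults and ``jeb`` for juveniles.  Females'
    calving clocks are staggered uniformly over one full calving cycle so
    that the initial population is not synchronized.
    """
    if n0_knp < 0 or n0_private < 0:
        raise ValueError("initial abundances must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    state = PopulationState(params, capacity=max(1024, int(1.7 * (n0_knp + n0_private))))
    dist = truncated_age_distribution(params)
    ppr = params.patches_per_subregion
    for sub, n0 in ((KNP, n0_knp), (PRIVATE, n0_private)):
        if n0 == 0:
            continue
        age = dist.rvs(size=n0, random_state=rng).astype(np.int32)
        np.maximum(age, 1, out=age)
        female = rng.random(n0) < 0.5
        gpatch = (sub * ppr + rng.integers(0, ppr, size=n0)).astype(np.int8)
        eb = np.where(age >= params.ma_weeks, params.meaneb, params.jeb).astype(
            np.float32
        )
        # stagger calving clocks over the expected calving cycle at the
        # initial patch density (intercalving wait + mean conception wait)
        x = (n0 / ppr) / (
            params.patch_capacity_knp if sub == KNP else params.patch_capacity_private
        )
        p = max(params.b0 * _density_response(np.array([x]), params)[0], 1e-4)
        cycle = params.intercalv_weeks + int(round(1.0 / p))
        wsc = np.where(
            female & (age >= params.ma_weeks),
            rng.integers(0, cycle, size=n0),
            age,
        ).astype(np.int32)
        state.append(age=age, sex_female=female, eb=eb, gpatch=gpatch, wsc=wsc)
    return state


def _density_response(x: np.ndarray, params: PopulationParams) -> np.ndarray:
    """Logistic decline of calving probability with relative density n/K."""
    return 1.0 / (1.0 + np.exp((x - params.dens_midpoint) / params.dens_slope))


def _sample_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, k: int
) -> np.ndarray:
    """k distinct elements of ``pool``; cheap for k << len(pool)."""
    n = len(pool)
    if k >= n:
        return pool
    if k > n // 4:
        return rng.choice(pool, size=k, replace=False)
    picked: set[int] = set()
    while len(picked) < k:
        for j in rng.integers(0, n, size=2 * (k - len(picked))):
            if j not in picked:
                picked.add(int(j))
                if len(picked) == k:
                    break
    return pool[np.fromiter(picked, dtype=np.int64, count=k)]


def weekly_step(
    state: PopulationState,
    av: float,
    poach_order,
    params: PopulationParams | None = None,
    rng: np.random.Generator | None = None,
    mean_av: float = 160.0,
) -> PopulationState:
    """Advance the population by one week in place; returns the state.

    ``av`` is this week's available vegetation (g/m^2) and ``mean_av`` its
    long-run mean; their ratio scales each patch's food supply.  The poach
    order is either a total count or a ``(m_knp, m_private)`` pair of mature
    animals to remove at random.  Demographic tallies for the week are left
    in ``state.last_counts``.
    """
    params = params or state.params
    rng = rng or np.random.default_rng(0)
    counts = StepCounts()
    state.week += 1
    n = state.n
    if n == 0:
        if isinstance(poach_order, (tuple, list)):
            counts.shortfall = int(sum(poach_order))
        else:
            counts.shortfall = int(poach_order)
        state.last_counts = counts
        return state

    status = state.status_[:n]
    alive = status == ALIVE
    age = state.age_[:n]
    wsc = state.wsc_[:n]
    age += alive
    wsc += alive
    gpatch = state.gpatch_[:n]

    # patch occupancy and food-supply ratio
    n_patches = params.n_subregions * params.patches_per_subregion
    occ = np.bincount(gpatch[alive], minlength=n_patches).astype(float)
    cap = _patch_capacities(params)
    av_ratio = max(av, 0.0) / mean_av
    supply = av_ratio * cap / np.maximum(occ, 1.0)   # per-capita intake / wfi

    # (2) energetics: replenish toward meb when intake is met, draw the
    # budget down by the shortfall fraction otherwise; exhausted budget kills
    noise = rng.standard_normal(n, dtype=np.float32)
    intake = supply[gpatch].astype(np.float32) * (1.0 + params.forage_noise_sd * noise)
    delta = np.clip(intake - 1.0, -1.0, 1.0)
    eb = state.eb_[:n]
    np.add(eb, delta, out=eb)
    starved = alive & (eb <= 0.0)
    np.clip(eb, 0.0, params.meb, out=eb)

    # (3) old age, plus density-dependent background natural mortality
    x = occ / cap
    mort_p = (
        params.base_weekly_mortality
        + params.dens_mortality_coef * x**params.dens_mortality_power
    ).astype(np.float32)
    dies = rng.random(n, dtype=np.float32) < mort_p[gpatch]
    dead_now = alive & (starved | (age >= params.le_weeks) | dies)
    status[dead_now] = DEAD_NATURAL
    counts.natural_deaths = int(dead_now.sum())
    alive &= ~dead_now

    # (4) births: eligible females calve with a density- and vegetation-
    # dependent weekly probability
    f_veg = np.clip(supply, 0.0, 1.0)
    birth_p = params.b0 * f_veg * _density_response(x, params)
    adult = age >= params.ma_weeks
    eligible = alive & state.sex_[:n] & adult & (wsc >= params.intercalv_weeks)
    # mate availability: calving requires an adult male in the sub-region
    ppr = params.patches_per_subregion
    males_by_sub = np.bincount(
        gpatch[alive & adult & ~state.sex_[:n]] // ppr,
        minlength=params.n_subregions,
    )
    if (males_by_sub == 0).any():
        eligible &= males_by_sub[gpatch // ppr] > 0
    idx_e = np.flatnonzero(eligible)
    if len(idx_e):
        birth_p32 = birth_p.astype(np.float32)
        mothers = idx_e[
            rng.random(len(idx_e), dtype=np.float32) < birth_p32[gpatch[idx_e]]
        ]
        nb = len(mothers)
        if nb:
            wsc[mothers] = 0
            state.append(
                age=np.zeros(nb, dtype=np.int32),
                sex_female=rng.random(nb) < 0.5,
                eb=np.full(nb, params.jeb, dtype=np.float32),
                gpatch=gpatch[mothers].copy(),
                wsc=np.zeros(nb, dtype=np.int32),
            )
            counts.births = nb
            # views may have been reallocated by append
            n = state.n
            status = state.status_[:n]
            age = state.age_[:n]
            alive = status == ALIVE
            adult = age >= params.ma_weeks

    # (5) poaching: remove mature animals uniformly at random.  Calves still
    # dependent on their mothers (younger than two years) are orphaned with
    # the same probability that adult females were removed from their
    # sub-region this week, and an orphan does not survive.
    if isinstance(poach_order, (tuple, list)):
        orders = list(poach_order)
    else:
        orders = [int(poach_order)]
    sub = state.gpatch_[:n] // params.patches_per_subregion
    whole_population = not isinstance(poach_order, (tuple, list))
    female = state.sex_[:n]
    mature_alive = alive & adult
    orphaned = 0
    for r, m in enumerate(orders):
        m = int(m)
        if m < 0:
            raise ValueError("poach order must be non-negative")
        if m == 0:
            continue
        region = np.ones(n, dtype=bool) if whole_population else (sub == r)
        cand = np.flatnonzero(mature_alive & region)
        take = _sample_without_replacement(rng, cand, min(m, len(cand)))
        status[take] = DEAD_POACHED
        counts.poached += len(take)
        counts.shortfall += m - len(take)
        if len(take):
            f_before = int((mature_alive & region & female).sum())
            f_taken = int(female[take].sum())
            if f_taken and f_before:
                calves = np.flatnonzero(
                    (status == ALIVE) & region & (age < _WEANING_WEEKS)
                )
                lost = calves[rng.random(len(calves)) < f_taken / f_before]
                status[lost] = DEAD_NATURAL
                orphaned += len(lost)
    counts.natural_deaths += orphaned
    state.cumulative_poached += counts.poached

    state.last_counts = counts
    state.maybe_compact()
    return state


def abundance(state: PopulationState) -> dict:
    """Exact alive counts by sub-region and in total."""
    alive = state.alive_mask()
    out = {name: 0 for name in _SUBREGION_NAMES.values()}
    if state.n:
        sub = state.subregion[alive]
        for code, name in _SUBREGION_NAMES.items():
            out[name] = int((sub == code).sum())
    out["total"] = sum(out[name] for name in _SUBREGION_NAMES.values())
    return out
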