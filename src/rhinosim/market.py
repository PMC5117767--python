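"""Agent-based sub-model of the rhino-horn market and its supply chain.

Two traders (one illegal, one legal when the policy allows trade) sell horn
to a pool of Asian consumer groups; each group buys exactly one kilogram per
purchase from the cheapest trader pricing at or below the $60,000/kg reserve
price.  The illegal trader is a meta-firm for the whole criminal syndicate
(middlemen through exporters); it keeps a sale inventory plus a speculation
stockpile fed by a fixed 5% hoarding rate, and never dumps below its
$5,000/kg unit cost.

Every 12-week cycle the sub-model converts demand into a poaching order:
``q_m`` kilograms of horn wanted implies ``q_m / 5`` attempted rhinos (a pair
of horns weighs ~5 kg), capped at 20 per week in Kruger plus 10 on private
ranches, thinned by the interception probability ``p_a``, reduced a further
5% by the SEAR (Species Extinction Anxiety Reduction) donation effect when a
week's order exceeds 30, and spread over the next 12 weeks as integer weekly
orders ``m``.

Intra-syndicate prices follow an "ask and bid" squeeze superimposed on
demand-driven market growth: each cycle poachers ask incrementally more and
the retailer bids incrementally less, eroding the middleman's margin share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import EconomicParams, PolicyScenario

__all__ = [
    "Trader",
    "SupplyChainState",
    "ConsumerPool",
    "StockAccounts",
    "MarketState",
    "WeeklyPoachOrder",
    "potential_consumers",
    "consumers_entering",
    "market_clearing",
    "allocate_supply",
    "squeeze_step",
    "market_drift",
    "economic_cycle",
    "weekly_sales",
    "sear_adjust",
    "unit_cost_breakdown",
]


@dataclass
class Trader:
    """A horn trader agent (the illegal one is the whole syndicate)."""

    kind: str                  # "legal" | "illegal"
    unit_cost: float = 5_000.0
    price: float = 60_000.0    # current ask to consumers, USD/kg
    inventory_kg: float = 0.0
    stockpile_kg: float = 0.0  # speculation stockpile, never sold
    maxcap: int = 35           # horns per cycle (replenishment capacity)

    def __post_init__(self) -> None:
        if self.price < self.unit_cost:
            raise ValueError("no dumping: ask price may not undercut unit cost")
        if self.inventory_kg < 0 or self.stockpile_kg < 0:
            raise ValueError("inventories must be non-negative")


@dataclass
class SupplyChainState:
    """Per-kilogram prices along the poacher-middleman-retailer chain."""

    poacher_ask: float         # price poachers demand, USD/kg
    middleman_price: float     # u_m, the middleman's offer to poachers
    retailer_bid: float        # u_r, the Asian retailer's offer to the middleman
    q_m_kg: float = 0.0        # kilograms demanded this cycle
    q_p: int = 0               # rhinos successfully poached this cycle

    def __post_init__(self) -> None:
        for name in ("poacher_ask", "middleman_price", "retailer_bid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def middleman_margin(self, shipping: float = 100.0) -> float:
        return self.retailer_bid - self.poacher_ask - shipping


@dataclass(frozen=True)
class ConsumerPool:
    """Weekly consumer-entry model; one consumer group buys exactly 1 kg.

    A "consumer" aggregates roughly 18-30 real-life purchase events.
    """

    n_pc: float                # potential consumer groups this week
    p_m: float                 # demand-reduction campaign effectiveness
    reserve_price: float = 60_000.0

    def __post_init__(self) -> None:
        if self.n_pc < 0:
            raise ValueError("n_pc must be non-negative")
        if not 0.0 <= self.p_m <= 1.0:
            raise ValueError("p_m must lie in [0, 1]")


@dataclass(frozen=True)
class StockAccounts:
    """One cycle's split of poached supply between inventory and hoard."""

    Q_T: float  # poached supply, kg
    R_T: float  # hoarded into the speculation stockpile, kg
    Y_T: float  # placed into sale inventory, kg


@dataclass(frozen=True)
class WeeklyPoachOrder:
    """The economic sub-model's output: weekly offtake for the next cycle."""

    weekly: tuple  # 12 pairs (m_knp, m_private)
    attempted: int  # attempts before interception thinning
    q_m_kg: float

    @property
    def total(self) -> int:
        return int(sum(k + p for k, p in self.weekly))


def _default_table2() -> pd.DataFrame:
    from .validation import load_tables

    return load_tables().table2


@lru_cache(maxsize=None)
def _pool_from_projection(year: int, base: int, cap: int) -> int:
    table2 = _default_table2()
    yrs = table2["year"].to_numpy(float)
    pops = table2["population"].to_numpy(float)
    pop = np.interp(min(year, 2040), yrs, pops)
    p2014 = np.interp(2014, yrs, pops)
    p2033 = np.interp(2033, yrs, pops)
    n = base + (cap - base) * (pop - p2014) / (p2033 - p2014)
    return int(round(min(max(n, base), cap)))


def potential_consumers(
    year: int,
    params: EconomicParams = EconomicParams(),
    table2: pd.DataFrame | None = None,
) -> int:
    """Potential consumer pool n_pc for a scenario year (2014 onward).

    300 groups in 2014, rising in proportion to the projected Asian
    population to a hard cap of 325 reached in 2033.
    """
    if year < 2014:
        raise ValueError(
            "potential_consumers covers the scenario epoch (>= 2014); "
            "validation runs use a demand model anchored to the observed "
            "poaching series"
        )
    if table2 is not None:
        yrs = table2["year"].to_numpy(float)
        pops = table2["population"].to_numpy(float)
        pop = np.interp(min(year, 2040), yrs, pops)
        p2014 = np.interp(2014, yrs, pops)
        p2033 = np.interp(2033, yrs, pops)
        base, cap = params.consumer_base_2014, params.consumer_max_2033
        n = base + (cap - base) * (pop - p2014) / (p2033 - p2014)
        return int(round(min(max(n, base), cap)))
    return _pool_from_projection(
        int(year), params.consumer_base_2014, params.consumer_max_2033
    )


def consumers_entering(
    n_pc: int, p_m: float, rng: np.random.Generator
) -> int:
    """One Binomial(n_pc, 1 - p_m) draw of consumers entering the market."""
    if n_pc < 0:
        raise ValueError("n_pc must be non-negative")
    if not 0.0 <= p_m <= 1.0:
        raise ValueError(f"p_m must lie in [0, 1], got {p_m}")
    return int(rng.binomial(int(n_pc), 1.0 - p_m))


def market_clearing(
    traders: Sequence[Trader],
    n_c: int,
    rng: np.random.Generator | None = None,
    reserve_price: float = 60_000.0,
) -> dict:
    """Sell 1 kg to each entering consumer from the cheapest priced trader.

    Consumers buy sequentially from the cheapest trader with positive
    inventory whose ask does not exceed the reserve price; ties resolve in
    listing order.  Returns kilograms sold per trader kind and the number of
    consumers who left unserved.
    """
    remaining = int(n_c)
    sales = {t.kind: 0.0 for t in traders}
    for trader in sorted(traders, key=lambda t: t.price):
        if remaining <= 0 or trader.price > reserve_price:
            break
        take = min(float(remaining), trader.inventory_kg)
        take = float(math.floor(take))  # whole 1-kg purchases
        if take > 0:
            trader.inventory_kg -= take
            sales[trader.kind] += take
            remaining -= int(take)
    sales["unmet"] = float(remaining)
    return sales


def allocate_supply(q_t_kg: float, hoarding_rate: float = 0.05) -> StockAccounts:
    """Split a cycle's poached supply: Y_T = Q_T - R_T with R_T = rate * Q_T."""
    if q_t_kg < 0:
        raise ValueError("poached supply must be non-negative")
    r = hoarding_rate * q_t_kg
    return StockAccounts(Q_T=q_t_kg, R_T=r, Y_T=q_t_kg - r)


def squeeze_step(
    chain: SupplyChainState,
    increment: float = 0.02,
    shipping: float = 100.0,
) -> SupplyChainState:
    """One cycle of ask-and-bid squeezing of the middleman's margin.

    The retailer offers an incrementally lower bid and poachers place an
    incrementally higher ask; the squeeze halts once the middleman's margin
    reaches zero (prices floor at participants' costs and never go negative).
    """
    new_bid = chain.retailer_bid * (1.0 - increment)
    new_ask = chain.poacher_ask * (1.0 + increment)
    if new_bid - new_ask - shipping < 0.0:
        return replace(chain)  # margin at floor: unchanged
    return replace(
        chain,
        retailer_bid=new_bid,
        poacher_ask=new_ask,
        middleman_price=new_ask * 1.05,
    )


def market_drift(chain: SupplyChainState, growth: float) -> SupplyChainState:
    """Scale the whole intra-syndicate price level by one cycle's growth."""
    if growth < 0:
        raise ValueError("growth factor must be non-negative")
    return replace(
        chain,
        poacher_ask=chain.poacher_ask * growth,
        middleman_price=chain.middleman_price * growth,
        retailer_bid=chain.retailer_bid * growth,
    )


def sear_adjust(m_week: int, threshold: int = 30, reduction: float = 0.05) -> int:
    """SEAR-market effect: weekly orders above ``threshold`` are cut 5%.

    Crisis-driven donations to conservation organizations buy a small extra
    margin of enforcement only when the poaching rate is severe (more than
    about the worst week Kruger has experienced).  Rounding is half-up.
    """
    if m_week < 0:
        raise ValueError("weekly poach order must be non-negative")
    if m_week > threshold:
        return int(math.floor(m_week * (1.0 - reduction) + 0.5))
    return int(m_week)


def unit_cost_breakdown(params: EconomicParams = EconomicParams()) -> dict:
    """Itemized USD/kg cost for the illegal trader to deliver one kilogram.

    Poachers are paid 5% of the lowest black-market price ($35,000/kg); a
    courier's airfare Maputo-Asia is $2,000 and the courier fee $500 per
    ~5 kg horn pair, i.e. $100/kg.
    """
    poacher_purchase = 0.05 * 35_000.0
    courier_airfare = 2_000.0
    courier_fee_per_kg = 500.0 / params.kg_per_rhino
    return {
        "poacher_purchase": poacher_purchase,
        "courier_airfare": courier_airfare,
        "courier_fee_per_kg": courier_fee_per_kg,
        "total": poacher_purchase + courier_airfare + courier_fee_per_kg,
        "conservative_unit_cost": params.unit_cost,
    }


# ---------------------------------------------------------------------------
# Market state and the 12-week economic cycle
# ---------------------------------------------------------------------------

@dataclass
class MarketState:
    """Mutable state of the economic sub-model between cycles."""

    params: EconomicParams
    traders: dict
    chain: SupplyChainState
    demand_model: Callable[[float], float] | None = None  # year -> weekly n_pc
    cycle_index: int = 0
    demand_kg: float = 0.0   # running totals within the current cycle
    sales_kg: float = 0.0
    unmet_kg: float = 0.0
    excess_ratio: float = 0.5  # previous cycle's unmet-demand fraction
    cum_poached_supply_kg: float = 0.0

    @classmethod
    def for_scenario(
        cls,
        scenario: PolicyScenario,
        params: EconomicParams = EconomicParams(),
    ) -> "MarketState":
        """2014-epoch market: prices at the 2014 anchors."""
        traders = {
            "illegal": Trader("illegal", params.unit_cost, price=60_000.0,
                              maxcap=params.maxcap_illegal),
        }
        if scenario.t:
            traders["legal"] = Trader(
                "legal", params.unit_cost, price=60_000.0, maxcap=params.maxcap_legal
            )
        chain = SupplyChainState(
            poacher_ask=1_700.0, middleman_price=1_785.0, retailer_bid=9_000.0
        )
        return cls(params=params, traders=traders, chain=chain)

    @classmethod
    def for_validation(
        cls,
        demand_model: Callable[[float], float],
        params: EconomicParams = EconomicParams(),
    ) -> "MarketState":
        """1998-epoch market: prices at late-1990s levels."""
        traders = {
            "illegal": Trader("illegal", params.unit_cost, price=5_000.0,
                              maxcap=params.maxcap_illegal),
        }
        chain = SupplyChainState(
            poacher_ask=30.0, middleman_price=31.5, retailer_bid=2_800.0
        )
        return cls(params=params, traders=traders, chain=chain, demand_model=demand_model)

    # -- demand ---------------------------------------------------------
    def weekly_potential_consumers(self, year: float, scenario: PolicyScenario) -> float:
        if self.demand_model is not None:
            return self.demand_model(year)
        n = potential_consumers(int(year), self.params)
        if self.params.consumer_pool_halved_without_trade and not scenario.t:
            n = n / 2.0
        return float(n)

    def receive_poached(self, q_p_rhinos: int) -> StockAccounts:
        """Book a cycle's poached supply into inventory and hoard."""
        accounts = allocate_supply(
            q_p_rhinos * self.params.kg_per_rhino, self.params.hoarding_rate
        )
        illegal = self.traders["illegal"]
        illegal.inventory_kg += accounts.Y_T
        illegal.stockpile_kg += accounts.R_T
        self.cum_poached_supply_kg += accounts.Q_T
        self.chain.q_p = q_p_rhinos
        return accounts

    def snapshot(self) -> dict:
        """Price/stock trace row for CSV export."""
        illegal = self.traders["illegal"]
        legal = self.traders.get("legal")
        return {
            "cycle": self.cycle_index,
            "poacher_ask": self.chain.poacher_ask,
            "u_m": self.chain.middleman_price,
            "u_r": self.chain.retailer_bid,
            "consumer_price_illegal": illegal.price,
            "consumer_price_legal": legal.price if legal else float("nan"),
            "sales_kg": self.sales_kg,
            "inventory_kg": illegal.inventory_kg,
            "stockpile_kg": illegal.stockpile_kg,
        }


def weekly_sales(
    market: MarketState,
    scenario: PolicyScenario,
    year: float,
    rng: np.random.Generator,
) -> dict:
    """One week of consumer entry and market clearing.

    Integer consumer pools draw Binomial(n_pc, 1 - p_m); the validation-mode
    demand model may be fractional, in which case entries are Poisson with
    the matching mean.
    """
    n_pc = market.weekly_potential_consumers(year, scenario)
    if float(n_pc).is_integer():
        n_c = consumers_entering(int(n_pc), scenario.p_m, rng)
    else:
        n_c = int(rng.poisson(n_pc * (1.0 - scenario.p_m)))
    sales = market_clearing(
        list(market.traders.values()), n_c, rng, market.params.reserve_price
    )
    market.demand_kg += n_c
    market.sales_kg += sum(v for k, v in sales.items() if k != "unmet")
    market.unmet_kg += sales["unmet"]
    return sales


def _update_prices(market: MarketState) -> None:
    """Cycle-boundary price dynamics: learning rule, drift, and squeeze."""
    p = market.params
    excess = market.unmet_kg / market.demand_kg if market.demand_kg > 0 else 0.0
    market.excess_ratio = excess
    for trader in market.traders.values():
        if market.demand_kg > 0 and excess > 0 and trader.inventory_kg < 1.0:
            trader.price = min(
                trader.price * (1.0 + p.learning_rate * excess),
                1.5 * p.reserve_price,
            )
        elif trader.inventory_kg >= 1.0 and market.demand_kg >= 0:
            leftover = trader.inventory_kg / max(
                trader.inventory_kg + market.sales_kg, 1.0
            )
            trader.price = max(
                trader.price * (1.0 - p.learning_rate * leftover), trader.unit_cost
            )
    growth = p.drift_base + p.drift_demand_gain * excess
    market.chain = market_drift(market.chain, growth)
    market.chain = squeeze_step(
        market.chain, p.squeeze_increment, p.shipping_cost_per_kg
    )


def _split_weekly_attempts(
    attempts_total: int, params: EconomicParams
) -> list:
    """Spread attempts over 12 weeks (remainder first) and across regions 2:1."""
    base, rem = divmod(attempts_total, 12)
    out = []
    for w in range(12):
        att = base + (1 if w < rem else 0)
        att = min(att, params.max_weekly_poach_total)
        knp = min(int(round(att * 2 / 3)), params.max_weekly_poach_knp)
        priv = min(att - knp, params.max_weekly_poach_private)
        knp = min(att - priv, params.max_weekly_poach_knp)
        out.append((knp, priv))
    return out


def economic_cycle(
    market: MarketState,
    scenario: PolicyScenario,
    year: float,
    rng: np.random.Generator,
) -> WeeklyPoachOrder:
    """Run one 12-week economic cycle and emit the weekly poach order.

    Demand-led restocking: the syndicate orders the horn it expects to sell
    over the next cycle net of its current inventory, converts kilograms to
    attempted rhinos (5 kg each), caps attempts at the 20 + 10 weekly maxima,
    thins each attempt by the interception probability ``p_a``, and applies
    the SEAR reduction to any week still above 30.  Trader prices and the
    intra-syndicate chain are updated from the previous cycle's outcome.
    """
    p = market.params
    if market.cycle_index > 0:
        _update_prices(market)
    market.demand_kg = market.sales_kg = market.unmet_kg = 0.0
    market.cycle_index += 1

    if "legal" in market.traders:
        # legal supply is stockpile/shavings replenishment, never poached
        legal = market.traders["legal"]
        legal.inventory_kg = legal.maxcap * (p.kg_per_rhino / 2.0)

    n_pc = market.weekly_potential_consumers(year, scenario)
    expected_weekly = n_pc * (1.0 - scenario.p_m)
    demand_kg = 12.0 * expected_weekly
    q_m = max(0.0, demand_kg - market.traders["illegal"].inventory_kg)
    market.chain.q_m_kg = q_m

    attempts_total = min(
        int(math.ceil(q_m / p.kg_per_rhino)), 12 * p.max_weekly_poach_total
    )
    weekly = []
    for att_knp, att_priv in _split_weekly_attempts(attempts_total, p):
        m_knp = int(rng.binomial(att_knp, 1.0 - scenario.p_a)) if att_knp else 0
        m_priv = int(rng.binomial(att_priv, 1.0 - scenario.p_a)) if att_priv else 0
        total = sear_adjust(m_knp + m_priv, p.sear_threshold, p.sear_reduction)
        cut = (m_knp + m_priv) - total
        m_knp = max(m_knp - cut, 0)  # SEAR cut lands on the larger KNP share
        weekly.append((m_knp, m_priv))
    return WeeklyPoachOrder(
        weekly=tuple(weekly), attempted=attempts_total, q_m_kg=q_m
    )
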