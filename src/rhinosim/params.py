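"""Named constants, parameter sets, and policy-scenario configuration.

Every number that the simulation treats as an empirical anchor lives here or
in the packaged data tables: the economics of the horn supply chain (unit
costs, reserve price, hoarding rate, trader capacities), white-rhino life
history (food intake, life expectancy, maturation, energetic budgets,
intercalving interval), and the policy vectors that define the strategic
response scenarios.

A policy scenario is the four-component vector (p_a, p_m, t, disruption):

* ``p_a``  -- probability that a poaching expedition is interdicted before it
  kills any rhino (0.04 realized; 0.10 status quo; 0.20 pro-active
  protection; 0.60 under criminal-network disruption),
* ``p_m``  -- effectiveness of a demand-reduction media campaign (consumers
  enter the market as Binomial(n_pc, 1 - p_m)),
* ``t``    -- whether a legal horn trader operates in parallel (0/1),
* ``disruption`` -- whether the transnational syndicate-disruption package
  (plus legal economic opportunities next to parks) is active; it always
  forces ``p_a = 0.60``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "PolicyScenario",
    "EconomicParams",
    "PopulationParams",
    "ScenarioError",
    "UnknownScenarioError",
    "ScenarioValidationError",
    "PRESET_NAMES",
    "load_scenario",
    "save_scenario",
    "iter_presets",
    "anti_poaching_effectiveness",
]

SCHEMA_VERSION = 1

#: Fields allowed in a scenario config document (fail-fast on anything else).
_SCENARIO_KEYS = {"schema_version", "name", "p_a", "p_m", "t", "disruption"}

#: Anti-poaching effectiveness under criminal-network disruption.
DISRUPTION_P_A = 0.60


class ScenarioError(ValueError):
    """Base class for scenario configuration problems."""


class UnknownScenarioError(ScenarioError, KeyError):
    """Raised when a preset name does not exist."""


class ScenarioValidationError(ScenarioError):
    """Raised when a scenario document fails validation."""


@dataclass(frozen=True)
class PolicyScenario:
    """A strategic-response scenario: the (p_a, p_m, t, disruption) vector."""

    name: str
    p_a: float
    p_m: float
    t: int
    disruption: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ScenarioValidationError(f"p_a must lie in [0, 1], got {self.p_a!r}")
        if not 0.0 <= self.p_m <= 1.0:
            raise ScenarioValidationError(f"p_m must lie in [0, 1], got {self.p_m!r}")
        if self.t not in (0, 1):
            raise ScenarioValidationError(f"t must be 0 or 1, got {self.t!r}")
        if self.disruption and not math.isclose(self.p_a, DISRUPTION_P_A):
            raise ScenarioValidationError(
                "disruption=true forces p_a = "
                f"{DISRUPTION_P_A}, got p_a={self.p_a}"
            )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "p_a": self.p_a,
            "p_m": self.p_m,
            "t": self.t,
            "disruption": self.disruption,
        }


@dataclass(frozen=True)
class EconomicParams:
    """Constants of the horn-market sub-model (all USD amounts per kilogram).

    ``sear_threshold``/``sear_reduction`` encode the Species Extinction
    Anxiety Reduction (SEAR) market effect: weekly poach orders above 30
    animals are cut by 5% to represent crisis-driven anti-poaching donations.
    """

    unit_cost: float = 5_000.0
    reserve_price: float = 60_000.0
    hoarding_rate: float = 0.05
    kg_per_rhino: float = 5.0
    max_weekly_poach_knp: int = 20
    max_weekly_poach_private: int = 10
    sear_threshold: int = 30
    sear_reduction: float = 0.05
    consumer_base_2014: int = 300
    consumer_max_2033: int = 325
    learning_rate: float = 0.4  # r_a, trader price-adjustment step
    maxcap_legal: int = 35      # horns per 12-week cycle
    maxcap_illegal: int = 35
    #: Open design switch: halve the potential-consumer pool when no legal
    #: trade operates (the 300 = 5 x 2 x 30 definition already contains the
    #: legal-trade doubling; default keeps 300 for every scenario).
    consumer_pool_halved_without_trade: bool = False
    # --- supply-chain price dynamics (calibrated, see docs/methods.md) ---
    squeeze_increment: float = 0.02    # per-cycle relative bid/ask squeeze
    drift_base: float = 1.030          # per-cycle market price growth floor
    drift_demand_gain: float = 0.016   # extra growth per unit excess demand
    shipping_cost_per_kg: float = 100.0

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "consumer_pool_halved_without_trade"
        }
        for key, value in numeric.items():
            if value < 0:
                raise ValueError(f"{key} must be non-negative, got {value}")
        if self.reserve_price <= self.unit_cost:
            raise ValueError("reserve_price must exceed unit_cost")
        if self.sear_threshold != self.max_weekly_poach_knp + self.max_weekly_poach_private:
            raise ValueError(
                "sear_threshold must equal the combined weekly poaching caps"
            )

    @property
    def max_weekly_poach_total(self) -> int:
        return self.max_weekly_poach_knp + self.max_weekly_poach_private


@dataclass(frozen=True)
class PopulationParams:
    """Life-history and demographic-rate parameters of the rhino sub-model.

    The first block mirrors the published reference values (energetic budgets
    are measured in weeks of reserve, after the prairie-vole formulation).
    The second block holds the density/vegetation response coefficients that
    are calibration targets rather than published constants: they are tuned
    so that an undisturbed high-density population realizes 7-8.5%/yr births
    and 1-2%/yr natural mortality, and a low-density population grows at the
    ~12%/yr implied by the validated 1998-2008 abundance trajectory.
    """

    wfi: float = 140.0          # kg fresh forage per rhino-week
    le: float = 38.0            # life expectancy, years
    ma: float = 4.0             # maturation age, years
    meb: float = 5.0            # maximum energetic budget, weeks
    meaneb: float = 4.0         # initial adult energetic budget, weeks
    jeb: float = 3.0            # juvenile energetic budget, weeks
    intercalv: float = 2.5      # minimum intercalving interval, years
    init_age_mean: float = 7.5  # years
    init_age_sd: float = 3.0    # years
    n_subregions: int = 2       # KNP and private ranches
    patches_per_subregion: int = 4
    # --- calibrated demographic response (docs/methods.md) ---
    b0: float = 0.0176               # weekly calving prob. of an eligible female, low density
    dens_midpoint: float = 0.525     # density (n/K) at which calving prob. halves
    dens_slope: float = 0.0827       # logistic width of the density response
    base_weekly_mortality: float = 1.8e-4
    dens_mortality_coef: float = 3.6e-4   # weekly hazard added at n = K
    dens_mortality_power: float = 2.0     # shape of the density ramp
    forage_noise_sd: float = 0.30         # individual foraging-success spread
    patch_capacity_knp: float = 4790.0    # rhinos fully fed per KNP patch at mean rainfall
    patch_capacity_private: float = 2055.0

    def __post_init__(self) -> None:
        if not (self.jeb <= self.meaneb <= self.meb):
            raise ValueError("energetic budgets must satisfy jeb <= meaneb <= meb")
        if not self.ma < self.le:
            raise ValueError("maturation age must precede life expectancy")
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    # -- convenience, weekly units used throughout the simulation --
    @property
    def le_weeks(self) -> int:
        return int(round(self.le * 52))

    @property
    def ma_weeks(self) -> int:
        return int(round(self.ma * 52))

    @property
    def intercalv_weeks(self) -> int:
        return int(round(self.intercalv * 52))


# ---------------------------------------------------------------------------
# Scenario presets and config loading
# ---------------------------------------------------------------------------

def _preset_dir():
    return resources.files("rhinosim.data") / "scenarios"


def _preset_names() -> tuple[str, ...]:
    names = sorted(
        p.name[: -len(".yaml")]
        for p in _preset_dir().iterdir()
        if p.name.endswith(".yaml")
    )
    return tuple(names)


PRESET_NAMES: tuple[str, ...] = _preset_names()


def _parse_scenario_mapping(doc: dict, origin: str) -> PolicyScenario:
    if not isinstance(doc, dict):
        raise ScenarioValidationError(f"{origin}: scenario document must be a mapping")
    unknown = set(doc) - _SCENARIO_KEYS
    if unknown:
        raise ScenarioValidationError(
            f"{origin}: unknown keys {sorted(unknown)}; allowed keys are "
            f"{sorted(_SCENARIO_KEYS)}"
        )
    missing = _SCENARIO_KEYS - set(doc)
    if missing:
        raise ScenarioValidationError(f"{origin}: missing keys {sorted(missing)}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ScenarioValidationError(
            f"{origin}: unsupported schema_version {doc['schema_version']!r}"
        )
    try:
        return PolicyScenario(
            name=str(doc["name"]),
            p_a=float(doc["p_a"]),
            p_m=float(doc["p_m"]),
            t=int(doc["t"]),
            disruption=bool(doc["disruption"]),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError(f"{origin}: {exc}") from exc


def load_scenario(source: str | Path) -> PolicyScenario:
    """Return a validated scenario from a preset name or a config file.

    ``source`` is first matched against the packaged preset table
    (:data:`PRESET_NAMES`); otherwise it is treated as a path to a YAML/JSON
    key-value document with the fields ``schema_version, name, p_a, p_m, t,
    disruption``.  Unknown keys are rejected.
    """
    key = str(source)
    if key in PRESET_NAMES:
        text = (_preset_dir() / f"{key}.yaml").read_text()
        return _parse_scenario_mapping(yaml.safe_load(text), origin=f"preset {key!r}")
    path = Path(source)
    if not path.exists():
        raise UnknownScenarioError(
            f"{key!r} is neither a preset ({', '.join(PRESET_NAMES)}) nor an "
            "existing config file"
        )
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioValidationError(f"{path}: unparseable config: {exc}") from exc
    return _parse_scenario_mapping(doc, origin=str(path))


def save_scenario(scenario: PolicyScenario, path: str | Path) -> None:
    """Write a scenario as a JSON round-trip document."""
    Path(path).write_text(json.dumps(scenario.to_dict(), indent=2) + "\n")


def iter_presets() -> Iterator[PolicyScenario]:
    for name in PRESET_NAMES:
        yield load_scenario(name)


# ---------------------------------------------------------------------------
# Derivation of the anti-poaching effectiveness parameter p_a
# ---------------------------------------------------------------------------

def anti_poaching_effectiveness() -> dict:
    """Reproduce the field-data derivation behind the p_a presets.

    2014 Kruger figures: an estimated 4,329 poacher entries (gangs of three),
    174 arrests (36 of whom were killed), 111 ranger contacts and 80
    sightings.  The realized interception rate is the 4% arrest chance; the
    status-quo scenario doubles it optimistically to 10%, pro-active
    protection doubles again to 20%, and network disruption represents a
    15-fold effectiveness increase at 60%.
    """
    poachers_entering = 4329
    arrests = 174
    killed = 36
    contacts = 111
    sightings = 80
    seen_or_contacted = (contacts + sightings) * 3
    return {
        "poachers_entering": poachers_entering,
        "arrests": arrests,
        "killed": killed,
        "contacts": contacts,
        "sightings": sightings,
        "seen_or_contacted": seen_or_contacted,
        "arrest_chance": arrests / poachers_entering,
        "kill_chance": killed / poachers_entering,
        "p_a_realized": 0.04,
        "p_a_status_quo": 0.10,
        "p_a_proactive": 0.20,
        "p_a_disruption": DISRUPTION_P_A,
    }
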