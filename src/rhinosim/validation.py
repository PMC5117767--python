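"""Packaged empirical tables and the model-validation statistics.

The printed tables travel with the package as plain CSV fixtures:

* table1 -- prices paid along the illegal supply chain, 2006-2014 (USD);
* table2 -- Asian population estimates/projections, 2010-2040;
* table3 -- rhinos poached and retail horn prices, 2009-2014;
* table4 -- average bid/ask ZAR-per-USD exchange rates, 2006-2014;
* table5 -- model parameters with reference values and valid intervals;
* table6 -- observed abundance estimates with 95% CIs vs model predictions,
  1998-2012 (no surveys in 2009 and 2011).

Validation statistics follow the published definitions: mean absolute
percentage error (MAPE) over the surveyed years, the count of predictions
inside the observed 95% confidence intervals, and the fraction of simulated
supply-chain prices falling inside the observed per-year price corridors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FixtureIntegrityError",
    "ValidationTables",
    "load_tables",
    "mape",
    "ci_coverage",
    "price_corridor_check",
    "zar_to_usd",
    "usd_per_zar",
]


class FixtureIntegrityError(ValueError):
    """A packaged table violates one of its structural invariants."""


@dataclass(frozen=True)
class ValidationTables:
    """Typed access to the packaged empirical tables."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    table6: pd.DataFrame

    # -- convenience accessors -----------------------------------------
    def surveyed_years(self) -> np.ndarray:
        t6 = self.table6.dropna(subset=["observed"])
        return t6["year"].to_numpy(dtype=int)

    def observed(self) -> np.ndarray:
        return self.table6.dropna(subset=["observed"])["observed"].to_numpy(float)

    def predicted(self) -> np.ndarray:
        return self.table6.dropna(subset=["observed"])["predicted"].to_numpy(float)

    def intervals(self) -> list:
        t6 = self.table6.dropna(subset=["observed"])
        return list(zip(t6["ci_low"].astype(float), t6["ci_high"].astype(float)))

    def middleman_corridors(self) -> dict:
        """Per-year (low, high) USD/kg paid to middlemen by retailers."""
        t1 = self.table1
        rows = t1[(t1["role"] == "middleman") & (t1["unit"] == "per_kg")]
        return {int(r.year): (float(r.low_usd), float(r.high_usd)) for r in rows.itertuples()}

    def poacher_corridors(self) -> dict:
        """Per-year (low, high) USD/kg paid to a three-man poaching team.

        Per-hunt team payments (water + axe carrier + shooter) convert to a
        per-kilogram corridor via the ~5 kg horn yield of one hunt.
        """
        t1 = self.table1
        out = {}
        poachers = t1[t1["role"].str.startswith("poacher") & (t1["unit"] == "per_hunt")]
        for year, grp in poachers.groupby("year"):
            g = grp.set_index("role")
            lo = float(g["low_usd"].sum()) / 5.0
            hi = float(g["high_usd"].sum()) / 5.0
            out[int(year)] = (lo, hi)
        return out


def _read(name: str) -> pd.DataFrame:
    with resources.files("rhinosim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def load_tables() -> ValidationTables:
    """Load all packaged tables and run the fixture-integrity checks."""
    tables = ValidationTables(
        table1=_read("table1_prices.csv"),
        table2=_read("table2_asian_population.csv"),
        table3=_read("table3_poaching_retail.csv"),
        table4=_read("table4_exchange_rates.csv"),
        table5=_read("table5_parameters.csv"),
        table6=_read("table6_abundance.csv"),
    )
    _check_integrity(tables)
    return tables


def _check_integrity(t: ValidationTables) -> None:
    if not t.table2["population"].is_monotonic_increasing:
        raise FixtureIntegrityError("Asian population projections must increase")
    if not t.table3["poached"].is_monotonic_increasing:
        raise FixtureIntegrityError("poached counts must increase 2009-2014")
    t6 = t.table6.dropna(subset=["observed"])
    bad = (t6["ci_low"] > t6["observed"]) | (t6["observed"] > t6["ci_high"])
    if bad.any():
        raise FixtureIntegrityError(
            f"CI bounds must bracket the point estimate (years "
            f"{t6.loc[bad, 'year'].tolist()})"
        )
    t5 = t.table5
    outside = (t5["value"] < t5["low"]) | (t5["value"] > t5["high"])
    if outside.any():
        raise FixtureIntegrityError(
            f"parameter reference values outside their valid intervals: "
            f"{t5.loc[outside, 'name'].tolist()}"
        )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def mape(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent.

    ``100 * mean(|pred_i - obs_i| / obs_i)`` over paired values; callers
    pass only the surveyed years.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs {obs.shape[0]} observations"
        )
    if np.any(obs == 0):
        raise ZeroDivisionError("observed values must be non-zero for MAPE")
    return float(100.0 * np.mean(np.abs(pred - obs) / np.abs(obs)))


def ci_coverage(
    predicted: Sequence[float], intervals: Sequence[tuple]
) -> int:
    """Count predictions inside their (inclusive) confidence intervals."""
    pred = np.asarray(predicted, dtype=float)
    if len(pred) != len(intervals):
        raise ValueError("predicted series and intervals must pair up")
    count = 0
    for p, (lo, hi) in zip(pred, intervals):
        if lo > hi:
            raise FixtureIntegrityError(f"interval ({lo}, {hi}) is inverted")
        if lo <= p <= hi:
            count += 1
    return count


def price_corridor_check(
    simulated_by_year: Mapping[int, float],
    corridors: Mapping[int, tuple],
) -> float:
    """Fraction of overlapping years with the simulated price in corridor."""
    years = sorted(set(simulated_by_year) & set(corridors))
    if not years:
        raise ValueError("no overlapping years between simulation and corridors")
    inside = sum(
        1
        for y in years
        if corridors[y][0] <= simulated_by_year[y] <= corridors[y][1]
    )
    return inside / len(years)


def zar_to_usd(amount_zar: float, year: int, table4: pd.DataFrame | None = None) -> float:
    """Convert Rand to USD with the year's average bid exchange rate."""
    table4 = load_tables().table4 if table4 is None else table4
    row = table4[table4["year"] == year]
    if row.empty:
        raise KeyError(f"no exchange rate on record for {year}")
    return float(amount_zar) / float(row["bid_zar_per_usd"].iloc[0])


def usd_per_zar(year: int, table4: pd.DataFrame | None = None) -> float:
    """The reciprocal bid rate (USD per ZAR) for a year."""
    return zar_to_usd(1.0, year, table4)
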