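"""Weekly rainfall and the available-vegetation proxy av(t).

Kruger rainfall is strongly seasonal (austral-summer wet season) with a slow
multi-year wet/dry modulation.  The simulation only needs rainfall as a
scaled proxy of available vegetation, so the series is generated from a
quasi-periodic harmonic model

    rain_w = max(0, a0 + a1 sin(2*pi*w/52 + phi1)
                     + a2 sin(2*pi*w/(52*P) + phi2) + eps_w),

with ``eps_w`` iid Gaussian noise.  Default coefficients put weekly means in
the 0-4 cm range with a clear annual cycle, matching the scale of the fitted
KNP predictions the model consumes.  Available vegetation is a linear
transform, ``av = scale * rain`` (g/m^2), so only the ratio of intake need to
availability matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RainfallParams", "RainfallSeries", "rainfall_series", "vegetation"]


@dataclass(frozen=True)
class RainfallParams:
    """Coefficients of the quasi-periodic weekly rainfall model."""

    annual_mean: float = 1.6      # a0, cm/week
    seasonal_amplitude: float = 0.6   # a1, annual harmonic
    slow_amplitude: float = 0.15      # a2, quasi-periodic modulation
    slow_period_years: float = 10.0   # P
    seasonal_phase: float = -np.pi / 2  # wet-season peak ~13 weeks into the year
    slow_phase: float = 0.0
    noise_sd: float = 0.25        # cm/week
    vegetation_scale: float = 100.0   # g/m^2 of new vegetation per cm of rain

    @property
    def mean_av(self) -> float:
        """Long-run mean available vegetation implied by the coefficients."""
        return self.vegetation_scale * self.annual_mean


@dataclass(frozen=True)
class RainfallSeries:
    """A weekly rainfall series and its vegetation transform."""

    week_index: np.ndarray   # integer weeks from simulation start
    rainfall: np.ndarray     # cm/week, >= 0
    av: np.ndarray           # available vegetation, g/m^2

    def __len__(self) -> int:
        return len(self.week_index)


def rainfall_series(
    n_weeks: int,
    seed: int | np.random.Generator,
    params: RainfallParams = RainfallParams(),
) -> RainfallSeries:
    """Generate ``n_weeks`` of non-negative weekly rainfall.

    Deterministic for a given seed and coefficient set.  The series carries a
    52-week seasonal cycle, a slow quasi-periodic modulation, and bounded
    Gaussian noise; negative excursions are clipped at zero.
    """
    if n_weeks < 1:
        raise ValueError(f"n_weeks must be >= 1, got {n_weeks}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = np.arange(n_weeks, dtype=float)
    base = (
        params.annual_mean
        + params.seasonal_amplitude * np.sin(2 * np.pi * w / 52 + params.seasonal_phase)
        + params.slow_amplitude
        * np.sin(2 * np.pi * w / (52 * params.slow_period_years) + params.slow_phase)
    )
    if params.noise_sd > 0:
        base = base + rng.normal(0.0, params.noise_sd, size=n_weeks)
    rain = np.maximum(base, 0.0)
    return RainfallSeries(
        week_index=np.arange(n_weeks),
        rainfall=rain,
        av=vegetation(rain, params.vegetation_scale),
    )


def vegetation(rainfall, scale: float = 100.0):
    """Available vegetation (g/m^2) as a linear scaling of rainfall (cm)."""
    rain = np.asarray(rainfall, dtype=float)
    if np.any(rain < 0):
        raise ValueError("rainfall must be non-negative")
    out = scale * rain
    if np.isscalar(rainfall) or out.ndim == 0:
        return float(out)
    return out


def to_frame(series: RainfallSeries):
    """Weekly series as a DataFrame (week, rainfall_cm, av) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "week": series.week_index,
            "rainfall_cm": series.rainfall,
            "av": series.av,
        }
    )
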