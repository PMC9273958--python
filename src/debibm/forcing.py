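"""Environmental and fishing forcings.

A :class:`ForcingSeries` carries hourly water temperature and food index
plus annual river-flow, rainfall and fishing-mortality values over the
simulation window, on a 365-day calendar (month = 1/12 year).  Forcings are
either read from CSV or produced by :func:`synthesize_forcings`, a seeded
generator emulating the conditions of the East China Sea hairtail habitat:
a sinusoidal seasonal temperature cycle with an interannual warming trend
and AR(1) anomalies, an autumn-peaked / winter-trough food index, annual
flow and rainfall anomalies around long-term means, and a piecewise annual
fishing-mortality series.

Scenario transforms shift temperature uniformly and scale fishing
mortality, leaving everything else bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "ForcingSeries",
    "ForcingConfig",
    "Scenario",
    "SCENARIOS",
    "flow_index",
    "rain_index",
    "expand_annual",
    "synthesize_forcings",
    "apply_scenario",
    "read_forcing_csv",
    "write_forcing_csv",
]

DAYS_PER_YEAR = 365.0
HOURS_PER_DAY = 24

CF_FLOW = 1e12  # river-flow anomaly correction factor [m^3]
CF_RAIN = 1.0   # rainfall anomaly correction factor [m]


def flow_index(flow_i: float, flow_mean: float) -> float:
    """Yangtze-flow anomaly index: (annual flow - long-term mean)/1e12 m^3."""
    return (flow_i - flow_mean) / CF_FLOW


def rain_index(rain_i: float, rain_mean: float) -> float:
    """Rainfall anomaly index: (annual rainfall - long-term mean)/1 m."""
    return (rain_i - rain_mean) / CF_RAIN


def expand_annual(values, grid, mode: str = "step"):
    """Expand a per-year series onto a sub-annual time grid [days].

    ``step`` holds each year's value constant within the calendar year;
    ``linear`` interpolates between year midpoints (clamped at the ends).
    Years are 365 days, year k covering [365k, 365(k+1)).
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    year_idx = np.floor(grid / DAYS_PER_YEAR).astype(int)
    if year_idx.min() < 0 or year_idx.max() >= len(values):
        raise ValueError(
            f"annual series covers years 0..{len(values) - 1} but the grid "
            f"spans years {year_idx.min()}..{year_idx.max()}")
    if mode == "step":
        return values[year_idx]
    if mode == "linear":
        mid = (np.arange(len(values)) + 0.5) * DAYS_PER_YEAR
        return np.interp(grid, mid, values)
    raise ValueError(f"unknown expansion mode {mode!r}")


@dataclass(frozen=True)
class ForcingSeries:
    """Forcing time series over the simulation window.

    ``time_days`` is the hourly grid (days since simulation start);
    per-step series align with it; annual series are indexed by simulation
    year (0-based).  ``K_food`` is the half-saturation constant mapping the
    food index onto the scaled functional response f = food/(food + K).
    """

    time_days: np.ndarray      # hourly grid [d]
    temperature_C: np.ndarray  # per step [deg C]
    food_index: np.ndarray     # per step [-]
    flow_m3: np.ndarray        # per year [m^3/y]
    rain_m: np.ndarray         # per year [m/y]
    Z_F_annual: np.ndarray     # per year [1/d]
    flow_mean: float           # long-term mean annual flow [m^3/y]
    rain_mean: float           # long-term mean annual rainfall [m/y]
    K_food: float = 2.4        # functional-response half saturation [-]
    zf_mode: str = "step"      # annual fishing-mortality expansion mode

    def __post_init__(self) -> None:
        n = len(self.time_days)
        if len(self.temperature_C) != n or len(self.food_index) != n:
            raise ValueError("per-step series must align with the time grid")
        if not np.all(np.isfinite(self.temperature_C)):
            raise ValueError("temperature contains non-finite values")
        if np.any(self.food_index < 0):
            raise ValueError("food index must be non-negative")
        if np.any(self.Z_F_annual < 0):
            raise ValueError("fishing mortality must be non-negative")
        n_years = int(np.ceil((self.time_days[-1] + 1e-9) / DAYS_PER_YEAR))
        for name in ("flow_m3", "rain_m", "Z_F_annual"):
            if len(getattr(self, name)) < n_years:
                raise ValueError(
                    f"annual series {name} does not cover the window "
                    f"({len(getattr(self, name))} yr < {n_years} yr)")

    @property
    def n_steps(self) -> int:
        return len(self.time_days)

    @property
    def n_years(self) -> int:
        return len(self.Z_F_annual)

    def functional_response(self) -> np.ndarray:
        """Scaled functional response per step: f = food/(food + K_food)."""
        return self.food_index / (self.food_index + self.K_food)

    def Z_F_steps(self) -> np.ndarray:
        """Fishing mortality expanded to the hourly grid [1/d]."""
        return expand_annual(self.Z_F_annual, self.time_days, self.zf_mode)

    def flow_index_annual(self) -> np.ndarray:
        return flow_index(self.flow_m3, self.flow_mean)

    def rain_index_annual(self) -> np.ndarray:
        return rain_index(self.rain_m, self.rain_mean)

    def slice_window(self, t0: float, t1: float) -> None:
        """Raise if [t0, t1] is not covered by the series."""
        if t0 < self.time_days[0] - 1e-9 or t1 > self.time_days[-1] + 1.0 / 24:
            raise ValueError(
                f"forcings cover [{self.time_days[0]:.3f}, "
                f"{self.time_days[-1]:.3f}] d but [{t0:.3f}, {t1:.3f}] d "
                "was requested")


@dataclass(frozen=True)
class Scenario:
    """A one-variable perturbation of the forcings."""

    label: str
    temperature_offset: float = 0.0   # uniform shift [deg C]
    fishing_multiplier: float = 1.0   # uniform Z_F scaling [-]

    def __post_init__(self) -> None:
        if self.fishing_multiplier < 0:
            raise ValueError("fishing multiplier must be non-negative")


#: The five standard scenarios plus the unperturbed baseline: warming
#: offsets for the 2100 GHG-emission pathways and +/-10% fishing effort.
SCENARIOS = {
    "baseline": Scenario("baseline"),
    "ssp1-1.9": Scenario("ssp1-1.9", temperature_offset=1.4),
    "ssp2-4.5": Scenario("ssp2-4.5", temperature_offset=2.7),
    "ssp5-8.5": Scenario("ssp5-8.5", temperature_offset=4.4),
    "zf+10": Scenario("zf+10", fishing_multiplier=1.1),
    "zf-10": Scenario("zf-10", fishing_multiplier=0.9),
}


def apply_scenario(forcings: ForcingSeries, scenario: Scenario) -> ForcingSeries:
    """Shift temperature and scale fishing mortality; all else unchanged."""
    return replace(
        forcings,
        temperature_C=forcings.temperature_C + scenario.temperature_offset,
        Z_F_annual=forcings.Z_F_annual * scenario.fishing_multiplier,
    )


# Default autumn-peaked, winter-trough monthly food profile (Jan..Dec).
_FOOD_PROFILE = (0.35, 0.35, 0.55, 0.75, 0.95, 1.10,
                 1.20, 1.30, 1.55, 1.60, 1.35, 0.60)


@dataclass(frozen=True)
class ForcingConfig:
    """Synthetic-forcing generator settings (the default study conditions).

    Temperature: mean 21 deg C with a 6 deg C seasonal amplitude (August
    maximum), the habitat's 15-27 deg C envelope; a slow warming trend and
    AR(1) daily anomalies.  Food: monthly profile peaking in autumn and
    lowest in winter, with lognormal interannual scaling; ``K_food`` sets
    the long-term mean functional response (~0.45 at the defaults).
    Fishing: piecewise-constant annual mortality around ``Z_F_base`` with
    lognormal interannual variation.  Flow and rainfall are annual draws
    around their long-term means.
    """

    years: int = 10
    mean_temperature_C: float = 21.0
    seasonal_amplitude_C: float = 6.0
    warming_slope_C_per_year: float = 0.02
    anomaly_sd_C: float = 0.4
    anomaly_ar1: float = 0.95
    peak_day_of_year: float = 215.0
    food_monthly: tuple[float, ...] = _FOOD_PROFILE
    food_year_sd: float = 0.10
    K_food: float = 2.4
    Z_F_base: float = 0.0055          # ~2 y^-1, the heavily fished regime
    Z_F_year_sd: float = 0.10
    flow_mean: float = 9.0e11         # Yangtze-scale annual discharge [m^3]
    flow_sd: float = 8.0e10
    rain_mean: float = 1.1            # annual rainfall [m]
    rain_sd: float = 0.15
    zf_mode: str = "step"

    def __post_init__(self) -> None:
        if self.years <= 0:
            raise ValueError("years must be positive")
        if self.seasonal_amplitude_C <= 0:
            raise ValueError("seasonal amplitude must be positive")
        if len(self.food_monthly) != 12:
            raise ValueError("food profile needs 12 monthly values")


def synthesize_forcings(config: ForcingConfig | None = None,
                        seed: int = 0) -> ForcingSeries:
    """Generate a seeded, reproducible forcing series."""
    cfg = ForcingConfig() if config is None else config
    rng = np.random.default_rng(seed)
    n_days = int(cfg.years * DAYS_PER_YEAR)
    grid = np.arange(n_days * HOURS_PER_DAY) / HOURS_PER_DAY

    seasonal = cfg.seasonal_amplitude_C * np.cos(
        2 * np.pi * (grid - cfg.peak_day_of_year) / DAYS_PER_YEAR)
    trend = cfg.warming_slope_C_per_year * grid / DAYS_PER_YEAR
    # AR(1) anomaly on the daily scale, held constant within each day
    innov_sd = cfg.anomaly_sd_C * np.sqrt(max(1.0 - cfg.anomaly_ar1**2, 0.0))
    daily = np.empty(n_days)
    x = rng.normal(0.0, cfg.anomaly_sd_C) if cfg.anomaly_sd_C > 0 else 0.0
    for i in range(n_days):
        daily[i] = x
        x = cfg.anomaly_ar1 * x + rng.normal(0.0, innov_sd) \
            if cfg.anomaly_sd_C > 0 else 0.0
    anomaly = np.repeat(daily, HOURS_PER_DAY)
    temperature = cfg.mean_temperature_C + seasonal + trend + anomaly

    # food: periodic interpolation of month-midpoint values, scaled by a
    # lognormal annual factor
    month_len = DAYS_PER_YEAR / 12.0
    mid = (np.arange(12) + 0.5) * month_len
    knots_t = np.concatenate(([mid[-1] - DAYS_PER_YEAR], mid,
                              [mid[0] + DAYS_PER_YEAR]))
    knots_v = np.concatenate(([cfg.food_monthly[-1]], cfg.food_monthly,
                              [cfg.food_monthly[0]]))
    doy = np.mod(grid, DAYS_PER_YEAR)
    food = np.interp(doy, knots_t, knots_v)
    year_of = np.floor(grid / DAYS_PER_YEAR).astype(int)
    food_factor = np.exp(rng.normal(0.0, cfg.food_year_sd, cfg.years)
                         - 0.5 * cfg.food_year_sd**2)
    food = food * food_factor[year_of]

    flow = cfg.flow_mean + rng.normal(0.0, cfg.flow_sd, cfg.years)
    rain = cfg.rain_mean + rng.normal(0.0, cfg.rain_sd, cfg.years)
    z_f = cfg.Z_F_base * np.exp(rng.normal(0.0, cfg.Z_F_year_sd, cfg.years)
                                - 0.5 * cfg.Z_F_year_sd**2)
    return ForcingSeries(time_days=grid, temperature_C=temperature,
                         food_index=food, flow_m3=np.maximum(flow, 0.0),
                         rain_m=np.maximum(rain, 0.0), Z_F_annual=z_f,
                         flow_mean=cfg.flow_mean, rain_mean=cfg.rain_mean,
                         K_food=cfg.K_food, zf_mode=cfg.zf_mode)


def write_forcing_csv(forcings: ForcingSeries, hourly_path, annual_path) -> None:
    """Write the hourly and annual CSV files."""
    pd.DataFrame({
        "timestamp_days": forcings.time_days,
        "temperature_C": forcings.temperature_C,
        "food_index": forcings.food_index,
    }).to_csv(hourly_path, index=False)
    pd.DataFrame({
        "year": np.arange(forcings.n_years),
        "flow_m3": forcings.flow_m3,
        "rain_m": forcings.rain_m,
        "Z_F_per_day": forcings.Z_F_annual,
    }).to_csv(annual_path, index=False)


def read_forcing_csv(hourly_path, annual_path, flow_mean: float | None = None,
                     rain_mean: float | None = None, K_food: float = 2.4,
                     zf_mode: str = "step") -> ForcingSeries:
    """Read forcings from the hourly/annual CSV pair.

    Long-term flow and rainfall means default to the means of the annual
    columns themselves.
    """
    hourly = pd.read_csv(hourly_path)
    annual = pd.read_csv(annual_path).sort_values("year")
    flow = annual["flow_m3"].to_numpy(float)
    rain = annual["rain_m"].to_numpy(float)
    return ForcingSeries(
        time_days=hourly["timestamp_days"].to_numpy(float),
        temperature_C=hourly["temperature_C"].to_numpy(float),
        food_index=hourly["food_index"].to_numpy(float),
        flow_m3=flow, rain_m=rain,
        Z_F_annual=annual["Z_F_per_day"].to_numpy(float),
        flow_mean=float(np.mean(flow)) if flow_mean is None else flow_mean,
        rain_mean=float(np.mean(rain)) if rain_mean is None else rain_mean,
        K_food=K_food, zf_mode=zf_mode)
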