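"""Daily driver series for the sulfur simulator.

Three concerns live here:

* turning sparse deposition measurements into daily series
  (:func:`prorate_wet_deposition`),
* extending short measured records across the 1770-2100 model timeframe
  with a day-of-year climatology scaled by a long-term emission index
  (:func:`extend_series_by_doy_climatology`,
  :func:`default_emission_index`),
* generating a fully synthetic, seeded forcing table
  (:func:`generate_synthetic_forcing`) whose columns are the contract the
  simulator consumes.  The generator stands in for an external water
  balance model: it runs a simple bucket (holding capacity, excess
  drains) that yields winter-high/summer-low soil moisture and
  winter-dominant percolation, a deciduous leaf-area cycle, autumn fog
  episodes and an SO2 record scaled by the emission index.

Forcing tables are plain :class:`pandas.DataFrame` objects with the
columns in :data:`FORCING_COLUMNS`; CSV round-tripping keeps full double
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .soil_processes import smoothstep

__all__ = [
    "FORCING_COLUMNS",
    "DailyForcing",
    "SyntheticForcingConfig",
    "prorate_wet_deposition",
    "extend_series_by_doy_climatology",
    "normalize_emission_index",
    "default_emission_index",
    "emission_index_at",
    "generate_synthetic_forcing",
    "validate_forcing",
    "read_forcing_csv",
    "write_forcing_csv",
]

#: Required columns of a forcing table, one row per day.
FORCING_COLUMNS = [
    "date", "doy", "precip", "fog_precip", "wet_dep", "so2_air",
    "infiltration", "bypass", "percolation", "theta", "soil_temp",
    "wind_u2", "kc_lai", "kc_stress", "doy_lc", "doy_le",
]

_NONNEGATIVE = ["precip", "fog_precip", "wet_dep", "so2_air",
                "infiltration", "bypass", "percolation", "wind_u2"]


@dataclass
class DailyForcing:
    """One day of drivers, unit-annotated; see :data:`FORCING_COLUMNS`.

    Water fluxes in mm/day, ``wet_dep`` in mg SO4-S m-2 d-1, ``so2_air``
    in mg SO2-S m-3, ``theta`` in L/L, ``soil_temp`` in deg C, ``wind_u2``
    in m/s.  ``kc_lai`` and ``kc_stress`` are dimensionless in [0, 1].
    """

    date: pd.Timestamp
    doy: int
    precip: float
    fog_precip: float
    wet_dep: float
    so2_air: float
    infiltration: float
    bypass: float
    percolation: float
    theta: float
    soil_temp: float
    wind_u2: float
    kc_lai: float
    kc_stress: float
    doy_lc: int
    doy_le: int


# ---------------------------------------------------------------------------
# proration of interval totals to daily values

def prorate_wet_deposition(
    biweekly_totals: Iterable[tuple],
    daily_precip: pd.Series,
) -> pd.Series:
    """Distribute interval deposition totals over days, proportional to
    daily precipitation.

    ``biweekly_totals`` is an iterable of ``((start, end), total)`` with
    inclusive date bounds and totals in mg SO4-S/m2; ``daily_precip`` is a
    daily series (mm) whose index covers every interval.  Interval sums
    are conserved exactly.  An interval whose precipitation sum is zero
    but whose total is not receives the total spread uniformly.
    """
    if not isinstance(daily_precip.index, pd.DatetimeIndex):
        daily_precip = daily_precip.copy()
        daily_precip.index = pd.DatetimeIndex(daily_precip.index)
    out = pd.Series(0.0, index=daily_precip.index)
    for interval, total in biweekly_totals:
        start, end = (pd.Timestamp(interval[0]), pd.Timestamp(interval[1]))
        if total < 0:
            raise ValueError(f"negative deposition total {total} for {start}..{end}")
        if start > end:
            raise ValueError(f"interval start {start} after end {end}")
        days = pd.date_range(start, end, freq="D")
        if not days.isin(daily_precip.index).all():
            raise ValueError(
                f"interval {start.date()}..{end.date()} not covered by the "
                "precipitation series")
        p = daily_precip.loc[days]
        if (p < 0).any():
            raise ValueError("negative precipitation in proration interval")
        psum = float(p.sum())
        if psum > 0.0:
            out.loc[days] = total * p / psum
        else:
            out.loc[days] = total / len(days)
    return out


# ---------------------------------------------------------------------------
# emission index and climatology extension

def normalize_emission_index(index: pd.Series, ref_years: Sequence[int]) -> pd.Series:
    """Normalize a year-indexed emission series to mean 1 over the
    reference period (the years with measured data)."""
    ref = index.loc[[y for y in ref_years if y in index.index]]
    if ref.empty:
        raise ValueError("no reference years present in the emission index")
    mean = float(ref.mean())
    if mean <= 0:
        raise ValueError("reference-period mean must be positive")
    return index / mean


#: Anchor points (year, relative level) of the default long-term SO2
#: emission trajectory for the region: near-constant pre-industrial
#: background, rise from 1880 to a peak around 1980, steep decline after
#: the late 1980s, and a current-legislation levelling-off after 2030.
_DEFAULT_EMISSION_ANCHORS = [
    (1880, 0.13), (1900, 0.35), (1920, 0.55), (1940, 0.70),
    (1960, 1.30), (1970, 1.75), (1980, 2.00), (1987, 1.85),
    (1995, 1.00), (2005, 0.55), (2012, 0.40), (2020, 0.30), (2030, 0.25),
]

#: Years with measured SO2 air concentration data, used to normalize the
#: default index to mean 1.
DEFAULT_REFERENCE_YEARS = range(1988, 2013)


def default_emission_index(years: "Sequence[int] | range" = range(1770, 2101)) -> pd.Series:
    """Year-indexed emission multiplier, normalized to mean 1 over the
    measured reference period; constant outside the anchor range
    (steady pre-industrial and post-legislation conditions)."""
    ys = np.asarray(list(years), dtype=int)
    ax = np.array([a[0] for a in _DEFAULT_EMISSION_ANCHORS], dtype=float)
    ay = np.array([a[1] for a in _DEFAULT_EMISSION_ANCHORS], dtype=float)
    vals = np.interp(ys.astype(float), ax, ay)  # constant beyond ends
    # normalization constant from the anchor curve over the reference
    # period, independent of the requested span
    ref_mean = np.interp(np.asarray(DEFAULT_REFERENCE_YEARS, float), ax, ay).mean()
    return pd.Series(vals / ref_mean, index=ys, name="index")


def emission_index_at(index: pd.Series, year: int) -> float:
    """Index value for a year, held constant before the first and after
    the last defined year."""
    if index.empty:
        raise ValueError("emission index is empty")
    if year in index.index:
        return float(index.loc[year])
    if year < index.index.min():
        return float(index.iloc[0])
    if year > index.index.max():
        return float(index.iloc[-1])
    # interior gap: linear interpolation
    return float(np.interp(year, index.index.to_numpy(float),
                           index.to_numpy(float)))


def extend_series_by_doy_climatology(
    measured: pd.Series,
    index: pd.Series,
    target_years: "Sequence[int] | range",
) -> pd.Series:
    """Extend a short daily record over arbitrary years.

    Outside the measured window each day receives the day-of-year mean of
    the measured record multiplied by the emission index of its year;
    inside the window the measured values are returned unchanged.  DoY
    366 falls back to the DoY 365 mean when no leap year was measured.
    """
    if measured.empty:
        raise ValueError("measured series is empty")
    measured = measured.copy()
    measured.index = pd.DatetimeIndex(measured.index)
    span_days = (measured.index.max() - measured.index.min()).days + 1
    if span_days < 365:
        raise ValueError("measured series must span at least one full year")
    clim = measured.groupby(measured.index.dayofyear).mean()
    if 366 not in clim.index:
        clim.loc[366] = clim.loc[365]

    years = list(target_years)
    dates = pd.date_range(f"{min(years)}-01-01", f"{max(years)}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    vals = clim.reindex(doy).to_numpy(float)
    idx_per_year = {y: emission_index_at(index, y) for y in
                    range(dates.year.min(), dates.year.max() + 1)}
    scale = np.array([idx_per_year[y] for y in dates.year])
    out = pd.Series(vals * scale, index=dates)
    inside = dates.isin(measured.index)
    out[inside] = measured.reindex(dates[inside]).to_numpy(float)
    return out


# ---------------------------------------------------------------------------
# synthetic forcing generator

@dataclass
class SyntheticForcingConfig:
    """Study conditions for the synthetic driver series.

    Defaults emulate the Vienna Woods beech stands: 660 mm annual
    precipitation, ~8 deg C mean soil temperature, a deciduous leaf cycle
    with autumn litterfall window, fog episodes in late autumn, and an
    SO2 record following the long-term emission index.  Years before
    ``weather_onset_year`` (the pre-industrial spin-up era) repeat a
    single climatological weather year so the spin-up can settle into a
    cyclo-stationary steady state.
    """

    start_year: int = 1770
    end_year: int = 2100
    annual_precip: float = 660.0          # mm/yr, scaled exactly
    mean_soil_temp: float = 8.0           # deg C, annual mean
    soil_temp_amplitude: float = 7.5      # deg C, seasonal half-range
    soil_temp_noise: float = 0.6          # deg C daily sd
    # soil / bucket
    z_r: float = 500.0                    # rooting depth, mm
    theta_residual: float = 0.05
    theta_sat: float = 0.45
    theta_fc: float = 0.30                # field capacity (holding threshold)
    drain_rate: float = 0.3               # fraction of excess drained per day
    bypass_frac: float = 0.10             # of precip on heavy-rain days
    bypass_threshold: float = 15.0        # mm/day
    pet_peak: float = 4.2                 # mm/day midsummer potential ET
    # phenology (DoY)
    leafout_start: int = 110
    leafout_end: int = 140
    doy_lc: int = 270
    doy_le: int = 300
    # precipitation process
    p_wet: float = 0.35                   # wet-day probability
    gamma_shape: float = 0.7              # wet-day amount distribution
    # fog episodes (late autumn)
    fog_doy_start: int = 274
    fog_doy_end: int = 360
    fog_events_per_autumn: float = 6.0
    fog_mm_mean: float = 1.5
    # chemistry (levels at emission index = 1)
    so2_mean: float = 0.004               # mg SO2-S m-3
    so2_seasonal_rel: float = 0.5         # winter-high relative amplitude
    so2_noise_sd: float = 0.25            # lognormal sigma
    wet_dep_conc: float = 0.9             # mg SO4-S per mm precipitation
    wind_mean: float = 2.0                # m/s
    weather_onset_year: int = 1880
    emission_index: "pd.Series | None" = None

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if self.annual_precip <= 0:
            raise ValueError("annual_precip must be positive")
        if not (self.theta_residual < self.theta_fc < self.theta_sat):
            raise ValueError("need theta_residual < theta_fc < theta_sat")
        if not self.doy_lc < self.doy_le:
            raise ValueError("litterfall window requires doy_lc < doy_le")


def _kc_lai(doy: int, cfg: SyntheticForcingConfig) -> float:
    if doy < cfg.leafout_start or doy > cfg.doy_le:
        return 0.0
    if doy < cfg.leafout_end:
        return smoothstep(doy, cfg.leafout_start, cfg.leafout_end, 0.0, 1.0)
    if doy < cfg.doy_lc:
        return 1.0
    return smoothstep(doy, cfg.doy_lc, cfg.doy_le, 1.0, 0.0)


def generate_synthetic_forcing(cfg: SyntheticForcingConfig, seed: int) -> pd.DataFrame:
    """Generate a seeded, reproducible forcing table for the configured
    span; see :class:`SyntheticForcingConfig` for the conditions."""
    rng = np.random.default_rng(seed)
    index = (cfg.emission_index if cfg.emission_index is not None
             else default_emission_index(range(cfg.start_year, cfg.end_year + 1)))

    dates = pd.date_range(f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-31",
                          freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    years = dates.year.to_numpy()

    # climatological template year (366 days), reused verbatim for every
    # pre-onset year; fresh draws afterwards
    tmpl_wet = rng.random(366) < cfg.p_wet
    tmpl_amt = rng.gamma(cfg.gamma_shape, 1.0, 366)
    tmpl_tnoise = rng.normal(0.0, cfg.soil_temp_noise, 366)
    tmpl_so2 = rng.lognormal(0.0, cfg.so2_noise_sd, 366)
    tmpl_wind = rng.gamma(4.0, cfg.wind_mean / 4.0, 366)
    tmpl_fog = np.zeros(366)
    fog_days = rng.integers(cfg.fog_doy_start, cfg.fog_doy_end + 1,
                            max(1, round(cfg.fog_events_per_autumn)))
    tmpl_fog[fog_days - 1] += rng.exponential(cfg.fog_mm_mean, len(fog_days))

    wet = rng.random(n) < cfg.p_wet
    amt = rng.gamma(cfg.gamma_shape, 1.0, n)
    tnoise = rng.normal(0.0, cfg.soil_temp_noise, n)
    so2_noise = rng.lognormal(0.0, cfg.so2_noise_sd, n)
    wind = rng.gamma(4.0, cfg.wind_mean / 4.0, n)
    fog = np.zeros(n)
    for y in range(max(cfg.start_year, cfg.weather_onset_year), cfg.end_year + 1):
        sel = years == y
        n_ev = rng.poisson(cfg.fog_events_per_autumn)
        if n_ev == 0:
            continue
        ev_doy = rng.integers(cfg.fog_doy_start, cfg.fog_doy_end + 1, n_ev)
        ev_mm = rng.exponential(cfg.fog_mm_mean, n_ev)
        offset = np.flatnonzero(sel)[0]
        for d, mm in zip(ev_doy, ev_mm):
            fog[offset + d - 1] += mm

    pre = years < cfg.weather_onset_year
    ti = doy - 1
    wet[pre] = tmpl_wet[ti[pre]]
    amt[pre] = tmpl_amt[ti[pre]]
    tnoise[pre] = tmpl_tnoise[ti[pre]]
    so2_noise[pre] = tmpl_so2[ti[pre]]
    wind[pre] = tmpl_wind[ti[pre]]
    fog[pre] = tmpl_fog[ti[pre]]

    precip = np.where(wet, amt, 0.0)
    # exact annual totals
    for y in range(cfg.start_year, cfg.end_year + 1):
        sel = years == y
        s = precip[sel].sum()
        if s > 0:
            precip[sel] *= cfg.annual_precip / s
        else:  # degenerate: all-dry draw, spread uniformly
            precip[sel] = cfg.annual_precip / sel.sum()

    # seasonal soil temperature (coldest early February)
    soil_temp = (cfg.mean_soil_temp
                 - cfg.soil_temp_amplitude * np.cos(2.0 * math.pi * (doy - 35) / 365.25)
                 + tnoise)

    idx_by_year = {y: emission_index_at(index, y)
                   for y in range(cfg.start_year, cfg.end_year + 1)}
    scale = np.array([idx_by_year[y] for y in years])
    so2 = (cfg.so2_mean
           * (1.0 + cfg.so2_seasonal_rel * np.cos(2.0 * math.pi * (doy - 15) / 365.25))
           * so2_noise * scale)
    wet_dep = cfg.wet_dep_conc * precip * scale

    # bucket water balance
    kc = np.array([_kc_lai(int(d), cfg) for d in range(1, 367)])
    kc_lai = kc[ti]
    pet = cfg.pet_peak * np.maximum(0.0, np.sin(2.0 * math.pi * (doy - 80) / 365.25)) ** 1.3

    z = cfg.z_r
    w = cfg.theta_fc * z
    w_res, w_fc, w_sat = cfg.theta_residual * z, cfg.theta_fc * z, cfg.theta_sat * z
    theta = np.empty(n)
    infiltration = np.empty(n)
    bypass = np.empty(n)
    percolation = np.empty(n)
    kc_stress = np.empty(n)
    for i in range(n):
        p = precip[i]
        byp = cfg.bypass_frac * p if p > cfg.bypass_threshold else 0.0
        inf = p - byp + fog[i]
        th = w / z
        stress = smoothstep(th, cfg.theta_residual + 0.03,
                            cfg.theta_residual + 0.12, 0.0, 1.0)
        aet = pet[i] * (0.3 + 0.7 * kc_lai[i]) * stress
        aet = min(aet, max(0.0, w - w_res) + inf)
        w = w + inf - aet
        perc = 0.0
        if w > w_fc:
            perc = cfg.drain_rate * (w - w_fc)
            w -= perc
        if w > w_sat:
            perc += w - w_sat
            w = w_sat
        theta[i] = w / z
        infiltration[i] = inf
        bypass[i] = byp
        percolation[i] = perc
        kc_stress[i] = stress

    df = pd.DataFrame({
        "date": dates,
        "doy": doy,
        "precip": precip,
        "fog_precip": fog,
        "wet_dep": wet_dep,
        "so2_air": so2,
        "infiltration": infiltration,
        "bypass": bypass,
        "percolation": percolation,
        "theta": theta,
        "soil_temp": soil_temp,
        "wind_u2": wind,
        "kc_lai": kc_lai,
        "kc_stress": kc_stress,
        "doy_lc": cfg.doy_lc,
        "doy_le": cfg.doy_le,
    })
    validate_forcing(df, theta_bounds=(cfg.theta_residual, cfg.theta_sat))
    return df


# ---------------------------------------------------------------------------
# validation and CSV round-tripping

def validate_forcing(df: pd.DataFrame,
                     theta_bounds: "tuple[float, float] | None" = None) -> None:
    """Raise ``ValueError`` when a forcing table violates its contract
    (missing columns, NaNs, negative fluxes, Kc outside [0, 1], ...)."""
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing table missing column(s): {', '.join(missing)}")
    for col in FORCING_COLUMNS:
        if col == "date":
            continue
        if df[col].isna().any():
            raise ValueError(f"forcing column {col!r} contains missing values")
    for col in _NONNEGATIVE:
        if (df[col].to_numpy(float) < 0).any():
            raise ValueError(f"forcing column {col!r} must be nonnegative")
    for col in ("kc_lai", "kc_stress"):
        v = df[col].to_numpy(float)
        if (v < 0).any() or (v > 1).any():
            raise ValueError(f"forcing column {col!r} must lie in [0, 1]")
    if theta_bounds is not None:
        lo, hi = theta_bounds
        th = df["theta"].to_numpy(float)
        if (th < lo - 1e-12).any() or (th > hi + 1e-12).any():
            raise ValueError(f"theta outside configured bounds [{lo}, {hi}]")
    if (df["doy_lc"].to_numpy() >= df["doy_le"].to_numpy()).any():
        raise ValueError("doy_lc must be below doy_le")
    dates = pd.DatetimeIndex(df["date"])
    if len(dates) > 1 and not (dates[1:] - dates[:-1] == pd.Timedelta("1D")).all():
        raise ValueError("forcing dates must be consecutive days")


def write_forcing_csv(df: pd.DataFrame, path) -> None:
    """Write a forcing table to CSV (ISO dates, full double precision)."""
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")


def read_forcing_csv(path) -> pd.DataFrame:
    """Read and validate a forcing table written by
    :func:`write_forcing_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: forcing CSV missing column(s): {', '.join(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    validate_forcing(df)
    return df
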