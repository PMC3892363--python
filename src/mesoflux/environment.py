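"""Synthetic environmental drivers: temperature, PAR, and rain.

The generator emulates the winter sensor record of the mesocosm plot: hourly
air temperature with a cooling seasonal trend, a diurnal sinusoid and AR(1)
weather noise; soil temperatures as exponentially smoothed (damped, lagged)
versions of air temperature; PAR as a clear-sky half-sine between local
sunrise and sunset scaled by a daily cloudiness factor and multiplicative
lognormal noise (unit mean); and a two-state Markov rain flag.

The noise-free limit is exactly the closed-form clear-sky / sinusoid curves,
which the tests use as the analytic reference.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd

from .config import SimConfig

ENV_COLUMNS = ["timestamp", "t_air_c", "t_surf_c", "t_soil2_c", "t_soil5_c",
               "par", "rain"]


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.rng_seed, spawn_key=(key,)))


def hourly_index(config: SimConfig) -> pd.DatetimeIndex:
    start = dt.datetime.combine(config.start_date, dt.time(0))
    end = dt.datetime.combine(config.end_date, dt.time(23))
    return pd.date_range(start, end, freq="h")


def day_length_hours(date: dt.date, latitude_deg: float) -> float:
    """Astronomical day length from the standard declination formula."""
    doy = date.timetuple().tm_yday
    decl = math.radians(-23.44) * math.cos(2 * math.pi * (doy + 10) / 365.0)
    lat = math.radians(latitude_deg)
    x = -math.tan(lat) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 24.0 / math.pi * math.acos(x)


def clear_sky_par(config: SimConfig, index: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic clear-sky PAR half-sine for each hourly timestamp."""
    par = np.zeros(len(index))
    for i, ts in enumerate(index):
        d = ts.date()
        length = day_length_hours(d, config.latitude_deg)
        rise = 12.0 - length / 2.0
        sets = 12.0 + length / 2.0
        h = ts.hour + 0.5  # hour-centre convention
        if rise < h < sets:
            doy = d.timetuple().tm_yday
            decl = math.radians(-23.44) * math.cos(2 * math.pi * (doy + 10) / 365.0)
            peak = config.par_peak_coeff * max(
                0.0, math.cos(math.radians(config.latitude_deg) - decl))
            par[i] = peak * math.sin(math.pi * (h - rise) / length)
    return par


def deterministic_temperature(config: SimConfig, index: pd.DatetimeIndex) -> np.ndarray:
    """Noise-free air temperature: linear seasonal trend + diurnal sinusoid
    peaking at 15:00 local."""
    n = len(index)
    frac = np.arange(n) / max(n - 1, 1)
    trend = config.t_mean_start_c + (config.t_mean_end_c - config.t_mean_start_c) * frac
    hours = index.hour.to_numpy() + 0.5
    diurnal = config.diurnal_amp_c * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    return trend + diurnal


def expected_mean_par(config: SimConfig) -> float:
    """Analytic long-run mean of generated PAR over the full record.

    The stochastic factors (daily cloudiness ~ U(cloud_min, cloud_max) and
    unit-mean lognormal hourly noise) enter multiplicatively, so the expected
    hourly mean is the deterministic clear-sky mean times the mean cloudiness.
    """
    clear = clear_sky_par(config, hourly_index(config))
    mean_cloud = 0.5 * (config.cloud_min + config.cloud_max)
    return float(clear.mean() * mean_cloud)


def generate_environment(config: SimConfig) -> pd.DataFrame:
    """Generate the hourly environmental series for the configured run.

    Returns a DataFrame with columns ``timestamp, t_air_c, t_surf_c,
    t_soil2_c, t_soil5_c, par, rain``; deterministic for a fixed
    ``config.rng_seed``. PAR is exactly zero outside local daylight.
    """
    config.validate()
    index = hourly_index(config)
    n = len(index)
    rng = _rng(config, 0)

    # air temperature: trend + diurnal + AR(1) noise
    t_det = deterministic_temperature(config, index)
    noise = np.zeros(n)
    if config.temp_noise_sd_c > 0:
        innov_sd = config.temp_noise_sd_c * math.sqrt(1 - config.temp_ar1_rho ** 2)
        eps = rng.normal(0.0, innov_sd, size=n)
        for i in range(1, n):
            noise[i] = config.temp_ar1_rho * noise[i - 1] + eps[i]
        noise[0] = rng.normal(0.0, config.temp_noise_sd_c)
    t_air = t_det + noise

    # soil temperatures: exponential smoothing of air temperature (damping + lag)
    def ema(series: np.ndarray, alpha: float) -> np.ndarray:
        out = np.empty_like(series)
        out[0] = series[0]
        for i in range(1, len(series)):
            out[i] = alpha * series[i] + (1 - alpha) * out[i - 1]
        return out

    t_surf = ema(t_air, 0.5)
    t_soil2 = ema(t_air, 0.25)
    t_soil5 = ema(t_air, 0.12)

    # PAR: clear-sky half-sine x daily cloudiness x unit-mean lognormal noise
    clear = clear_sky_par(config, index)
    days = index.normalize()
    unique_days = days.unique()
    cloud_by_day = dict(zip(
        unique_days,
        rng.uniform(config.cloud_min, config.cloud_max, size=len(unique_days))))
    cloud = np.array([cloud_by_day[d] for d in days])
    if config.par_lognorm_sigma > 0:
        sigma = config.par_lognorm_sigma
        lognoise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=n)
    else:
        lognoise = np.ones(n)
    par = clear * cloud * lognoise

    # rain: two-state Markov chain on hours
    rain = np.zeros(n, dtype=bool)
    u = rng.random(n)
    wet = False
    for i in range(n):
        p = config.rain_p_wet_given_wet if wet else config.rain_p_wet_given_dry
        wet = u[i] < p
        rain[i] = wet

    return pd.DataFrame({
        "timestamp": index,
        "t_air_c": t_air,
        "t_surf_c": t_surf,
        "t_soil2_c": t_soil2,
        "t_soil5_c": t_soil5,
        "par": par,
        "rain": rain,
    })


def validate_environment(env: pd.DataFrame) -> None:
    """Check the EnvSeries invariants; raise ValueError on violation."""
    missing = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing:
        raise ValueError(f"environment frame missing columns: {missing}")
    if env["timestamp"].isna().any():
        raise ValueError("missing timestamps")
    diffs = env["timestamp"].diff().dropna()
    if not (diffs == pd.Timedelta(hours=1)).all():
        raise ValueError("timestamps must be a gap-free hourly grid")
    if (env["par"] < 0).any():
        raise ValueError("PAR must be non-negative")
    if not np.isfinite(env[["t_air_c", "t_surf_c", "t_soil2_c", "t_soil5_c", "par"]]
                       .to_numpy()).all():
        raise ValueError("non-finite environment values")
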