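"""Closed dynamic chamber flux estimation from raw CO2 closure traces.

Each chamber closure yields a 1 Hz CO2 concentration trace. The flux is the
ordinary-least-squares slope of concentration against time over a fixed
calculation window that starts after a chamber-type-specific "dead band"
(opaque chambers need a longer one because photosynthesis continues briefly
after darkening), converted to an areal molar flux through the ideal-gas
head-space equation. Sign follows the micrometeorological convention:
positive = net release to the atmosphere.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .config import R_GAS, RunConfig

#: calculation window applied after the dead band, seconds
DEFAULT_WINDOW_S = 90.0
#: dead band per chamber type, seconds
DEADBANDS_S = {"opaque": 50.0, "transparent": 20.0}

TRACE_COLUMNS = ["closure_id", "collar_id", "chamber_type", "timestamp",
                 "t_s", "co2_ppm", "par_in", "par_out", "t_air_c"]

FLUX_COLUMNS = ["closure_id", "collar_id", "chamber_type", "timestamp",
                "flux", "slope", "r2", "slope_se", "deadband_s", "window_s",
                "par_in", "par_out", "temperature_c", "qc_flags"]


class TraceFitError(ValueError):
    """Raised when a trace cannot support the requested fit window."""


@dataclass
class ChamberTrace:
    """One closure's raw CO2 series plus chamber geometry and ambient state."""

    closure_id: str
    collar_id: str
    chamber_type: str  # "transparent" | "opaque"
    timestamp: dt.datetime
    t: np.ndarray  # seconds since closure, strictly increasing from 0
    co2: np.ndarray  # ppm (umol mol-1, dry)
    volume_m3: float
    area_m2: float
    t_air_c: float
    pressure_pa: float
    par_in: float = 0.0
    par_out: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.chamber_type not in DEADBANDS_S:
            raise ValueError(f"unknown chamber type {self.chamber_type!r}")
        if self.t.size == 0 or self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing from 0")
        if self.t.size != self.co2.size:
            raise ValueError("t and co2 must have equal length")
        if np.any(self.co2 <= 0):
            raise ValueError("co2 must be positive")
        for name in ("volume_m3", "area_m2", "pressure_pa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FluxRecord:
    """One computed flux (umol CO2 m-2 s-1, positive = release) with QC."""

    closure_id: str
    collar_id: str
    chamber_type: str
    timestamp: dt.datetime
    flux: float
    slope: float  # ppm s-1
    r2: float
    slope_se: float
    deadband_s: float
    window_s: float
    par_in: float
    par_out: float
    temperature_c: float
    qc_flags: set[str] = field(default_factory=set)


def default_deadband(chamber_type: str) -> float:
    """Dead band in seconds: 50 for opaque, 20 for transparent chambers."""
    try:
        return DEADBANDS_S[chamber_type]
    except KeyError:
        raise ValueError(f"unknown chamber type {chamber_type!r}") from None


def _window_mask(t: np.ndarray, deadband_s: float, window_s: float) -> np.ndarray:
    # half-open interval [deadband, deadband + window)
    return (t >= deadband_s) & (t < deadband_s + window_s)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, r2 and slope SE of an OLS line fit (mean-centred form)."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 0.0
    if n > 2:
        rss = max(syy - slope * sxy, 0.0)
        se = float(np.sqrt(rss / ((n - 2) * sxx)))
    else:
        se = float("nan")
    return slope, min(max(r2, 0.0), 1.0), se


def fit_trace_slope(trace: ChamberTrace, deadband_s: float | None = None,
                    window_s: float = DEFAULT_WINDOW_S) -> tuple[float, float, float]:
    """OLS slope (ppm s-1), r2 and slope SE over [deadband, deadband+window).

    Raises :class:`TraceFitError` if the trace does not cover the window or
    holds fewer than 10 samples in it; a failed fit is never a silent zero.
    """
    if deadband_s is None:
        deadband_s = default_deadband(trace.chamber_type)
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if trace.t[-1] < deadband_s + window_s - 1.0:
        raise TraceFitError(
            f"trace {trace.closure_id}: duration {trace.t[-1]:.0f}s does not "
            f"cover dead band {deadband_s:.0f}s + window {window_s:.0f}s")
    mask = _window_mask(trace.t, deadband_s, window_s)
    if mask.sum() < 10:
        raise TraceFitError(
            f"trace {trace.closure_id}: only {int(mask.sum())} samples in window")
    return _ols_line(trace.t[mask], trace.co2[mask])


def concentration_slope_to_flux(slope_ppm_s: float, volume_m3: float,
                                area_m2: float, temperature_k: float,
                                pressure_pa: float) -> float:
    """Ideal-gas head-space conversion: F = slope * P V / (R T A).

    A slope in umol mol-1 s-1 (ppm s-1) yields a flux in umol m-2 s-1.
    """
    args = (slope_ppm_s, volume_m3, area_m2, temperature_k, pressure_pa)
    if not all(np.isfinite(args)):
        raise ValueError("non-finite input to flux conversion")
    if volume_m3 <= 0 or area_m2 <= 0 or temperature_k <= 0 or pressure_pa <= 0:
        raise ValueError("V, A, T, P must all be positive")
    return slope_ppm_s * pressure_pa * volume_m3 / (R_GAS * temperature_k * area_m2)


def flux_to_concentration_slope(flux: float, volume_m3: float, area_m2: float,
                                temperature_k: float, pressure_pa: float) -> float:
    """Exact inverse of :func:`concentration_slope_to_flux` (ppm s-1)."""
    return flux * R_GAS * temperature_k * area_m2 / (pressure_pa * volume_m3)


def fit_record(trace: ChamberTrace, config: RunConfig | None = None) -> FluxRecord:
    """Fit one trace into a :class:`FluxRecord` using configured dead bands."""
    config = config or RunConfig()
    deadband = (config.deadband_opaque_s if trace.chamber_type == "opaque"
                else config.deadband_transparent_s)
    flags: set[str] = set()
    try:
        slope, r2, se = fit_trace_slope(trace, deadband, config.window_s)
        flux = concentration_slope_to_flux(
            slope, trace.volume_m3, trace.area_m2,
            trace.t_air_c + 273.15, trace.pressure_pa)
    except TraceFitError:
        slope = r2 = se = flux = float("nan")
        flags.add("fit_failed")
    return FluxRecord(
        closure_id=trace.closure_id, collar_id=trace.collar_id,
        chamber_type=trace.chamber_type, timestamp=trace.timestamp,
        flux=flux, slope=slope, r2=r2, slope_se=se,
        deadband_s=deadband, window_s=config.window_s,
        par_in=trace.par_in, par_out=trace.par_out,
        temperature_c=trace.t_air_c, qc_flags=flags)


# ---------------------------------------------------------------------------
# batch container


@dataclass
class TraceSet:
    """A set of equal-length closures: per-closure metadata plus a 2D CO2
    matrix (closures x seconds). The memory-efficient batch counterpart of a
    list of :class:`ChamberTrace`."""

    meta: pd.DataFrame  # closure_id, collar_id, chamber_type, timestamp,
    #                     volume_m3, area_m2, t_air_c, pressure_pa, par_in, par_out
    t: np.ndarray  # shared time axis, seconds
    co2: np.ndarray  # shape (len(meta), len(t))

    def __post_init__(self) -> None:
        if self.co2.shape != (len(self.meta), self.t.size):
            raise ValueError("co2 matrix shape mismatch")

    def __len__(self) -> int:
        return len(self.meta)

    def iter_traces(self) -> Iterator[ChamberTrace]:
        for i, row in enumerate(self.meta.itertuples(index=False)):
            yield ChamberTrace(
                closure_id=row.closure_id, collar_id=row.collar_id,
                chamber_type=row.chamber_type,
                timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
                t=self.t, co2=self.co2[i],
                volume_m3=row.volume_m3, area_m2=row.area_m2,
                t_air_c=row.t_air_c, pressure_pa=row.pressure_pa,
                par_in=row.par_in, par_out=row.par_out)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format frame matching the ``traces.csv`` dialect."""
        n, m = self.co2.shape
        rep = self.meta.loc[self.meta.index.repeat(m)].reset_index(drop=True)
        out = pd.DataFrame({
            "closure_id": rep["closure_id"],
            "collar_id": rep["collar_id"],
            "chamber_type": rep["chamber_type"],
            "timestamp": rep["timestamp"],
            "t_s": np.tile(self.t, n),
            "co2_ppm": self.co2.ravel(),
            "par_in": rep["par_in"],
            "par_out": rep["par_out"],
            "t_air_c": rep["t_air_c"],
        })
        out["volume_m3"] = rep["volume_m3"]
        out["area_m2"] = rep["area_m2"]
        out["pressure_pa"] = rep["pressure_pa"]
        return out

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "TraceSet":
        required = set(TRACE_COLUMNS) | {"volume_m3", "area_m2", "pressure_pa"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"trace frame missing columns: {sorted(missing)}")
        groups = frame.groupby("closure_id", sort=False)
        t_ref = None
        metas, rows = [], []
        for cid, g in groups:
            g = g.sort_values("t_s")
            t = g["t_s"].to_numpy(dtype=float)
            if t_ref is None:
                t_ref = t
            elif t.size != t_ref.size or not np.array_equal(t, t_ref):
                raise ValueError("all closures must share one time axis")
            rows.append(g["co2_ppm"].to_numpy(dtype=float))
            first = g.iloc[0]
            metas.append({k: first[k] for k in
                          ("closure_id", "collar_id", "chamber_type", "timestamp",
                           "volume_m3", "area_m2", "t_air_c", "pressure_pa",
                           "par_in", "par_out")})
        meta = pd.DataFrame(metas)
        meta["timestamp"] = pd.to_datetime(meta["timestamp"])
        return cls(meta=meta, t=t_ref, co2=np.vstack(rows))


def fit_traces(traces: TraceSet, config: RunConfig | None = None) -> pd.DataFrame:
    """Vectorised per-closure OLS fit of a :class:`TraceSet`.

    Returns a flux-record frame (one row per closure) identical, value for
    value, to looping :func:`fit_record` over the individual traces.
    """
    config = config or RunConfig()
    meta = traces.meta
    n = len(meta)
    deadbands = np.where(meta["chamber_type"].to_numpy() == "opaque",
                         config.deadband_opaque_s, config.deadband_transparent_s)
    slope = np.full(n, np.nan)
    r2 = np.full(n, np.nan)
    se = np.full(n, np.nan)
    failed = np.zeros(n, dtype=bool)
    for db in np.unique(deadbands):
        sel = deadbands == db
        mask = _window_mask(traces.t, db, config.window_s)
        if traces.t[-1] < db + config.window_s - 1.0 or mask.sum() < 10:
            failed |= sel
            continue
        x = traces.t[mask]
        y = traces.co2[np.ix_(sel, mask)]
        m = x.size
        xc = x - x.mean()
        sxx = float(xc @ xc)
        yc = y - y.mean(axis=1, keepdims=True)
        sxy = yc @ xc
        syy = np.einsum("ij,ij->i", yc, yc)
        sl = sxy / sxx
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = np.where(syy > 0, (sxy * sxy) / (sxx * syy), 0.0)
        rss = np.maximum(syy - sl * sxy, 0.0)
        ss = np.sqrt(rss / ((m - 2) * sxx))
        slope[sel] = sl
        r2[sel] = np.clip(rr, 0.0, 1.0)
        se[sel] = ss
    t_k = meta["t_air_c"].to_numpy() + 273.15
    flux = slope * meta["pressure_pa"].to_numpy() * meta["volume_m3"].to_numpy() / (
        R_GAS * t_k * meta["area_m2"].to_numpy())
    out = pd.DataFrame({
        "closure_id": meta["closure_id"],
        "collar_id": meta["collar_id"],
        "chamber_type": meta["chamber_type"],
        "timestamp": pd.to_datetime(meta["timestamp"]),
        "flux": flux, "slope": slope, "r2": r2, "slope_se": se,
        "deadband_s": deadbands,
        "window_s": config.window_s,
        "par_in": meta["par_in"], "par_out": meta["par_out"],
        "temperature_c": meta["t_air_c"],
        "qc_flags": np.where(failed, "fit_failed", ""),
    })
    out.loc[failed, ["flux", "slope", "r2", "slope_se"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# QC and pairing


_KNOWN_QC_KEYS = {"night_par_threshold", "r2_threshold", "slope_noise_floor_ppm_s"}


def qc_filter(records: pd.DataFrame, env: pd.DataFrame | None = None,
              **rules: float) -> pd.DataFrame:
    """Attach QC flags (``night``, ``rain``, ``poor_fit``) without deleting rows.

    ``night``: par_out below the night threshold. ``rain``: the closure hour is
    flagged rainy in the environment log. ``poor_fit``: r2 below threshold,
    applied only when |slope| exceeds a noise floor (a flat trace from a truly
    tiny flux legitimately has low r2). Unknown rule keys are rejected.
    """
    unknown = set(rules) - _KNOWN_QC_KEYS
    if unknown:
        raise ValueError(f"unknown QC rule keys: {sorted(unknown)}")
    night_thr = rules.get("night_par_threshold", 5.0)
    r2_thr = rules.get("r2_threshold", 0.75)
    floor = rules.get("slope_noise_floor_ppm_s", 0.005)

    out = records.copy()
    flags = out["qc_flags"].fillna("").astype(str).str.split(";").apply(
        lambda xs: {x for x in xs if x})
    night = out["par_out"].to_numpy() < night_thr
    poor = (out["r2"].to_numpy() < r2_thr) & (np.abs(out["slope"].to_numpy()) > floor)
    rain = np.zeros(len(out), dtype=bool)
    if env is not None:
        rain_by_hour = env.set_index(pd.to_datetime(env["timestamp"]))["rain"]
        hours = pd.to_datetime(out["timestamp"]).dt.floor("h")
        mapped = hours.map(rain_by_hour)
        rain = np.where(pd.isna(mapped), False, mapped).astype(bool)
    for i, fs in enumerate(flags):
        if night[i]:
            fs.add("night")
        if rain[i]:
            fs.add("rain")
        if poor[i]:
            fs.add("poor_fit")
    out["qc_flags"] = [";".join(sorted(fs)) for fs in flags]
    return out


def has_flag(records: pd.DataFrame, flag: str) -> pd.Series:
    return records["qc_flags"].fillna("").str.split(";").apply(lambda xs: flag in xs)


class PairingError(ValueError):
    """Two same-type closures in one collar-hour."""


def pair_cycle(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each transparent closure with the opaque closure that follows it
    within the same collar-hour.

    Returns ``(pairs, unpaired)``. ``pairs`` has one row per collar-hour with
    ``nee`` (transparent flux), ``reco`` (opaque flux) and shared metadata;
    hours with only one chamber type keep the other column as NaN and are
    also listed in ``unpaired``. Duplicate same-type closures in a collar-hour
    raise :class:`PairingError` naming the closures.
    """
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    rec = rec.sort_values("timestamp")
    rec["hour"] = rec["timestamp"].dt.floor("h")
    dup = rec.duplicated(subset=["collar_id", "hour", "chamber_type"], keep=False)
    if dup.any():
        ids = rec.loc[dup, "closure_id"].tolist()
        raise PairingError(f"ambiguous closures in one collar-hour: {ids}")

    wide = rec.pivot(index=["collar_id", "hour"], columns="chamber_type",
                     values="flux")
    meta_cols = ["par_out", "par_in", "temperature_c", "qc_flags"]
    pairs = wide.reset_index().rename(
        columns={"transparent": "nee", "opaque": "reco"})
    for col in ("nee", "reco"):
        if col not in pairs.columns:
            pairs[col] = np.nan
    # transparent must precede the opaque closure inside the hour
    order = rec.pivot(index=["collar_id", "hour"], columns="chamber_type",
                      values="timestamp")
    if "transparent" in order.columns and "opaque" in order.columns:
        both = order.dropna()
        bad = both["transparent"] >= both["opaque"]
        if bad.any():
            raise PairingError(
                f"opaque closure precedes transparent in hours: "
                f"{both.index[bad].tolist()[:5]}")

    for col in meta_cols:
        side = rec[rec["chamber_type"] == "transparent"]
        fallback = rec[rec["chamber_type"] == "opaque"]
        m = pd.concat([side, fallback]).drop_duplicates(
            subset=["collar_id", "hour"], keep="first")
        pairs[col] = pairs.set_index(["collar_id", "hour"]).index.map(
            m.set_index(["collar_id", "hour"])[col])
    pairs = pairs.rename(columns={"hour": "timestamp"})
    unpaired = pairs[pairs["nee"].isna() | pairs["reco"].isna()].copy()
    return pairs, unpaired
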