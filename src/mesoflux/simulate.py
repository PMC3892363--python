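"""Forward mesocosm simulator with enforced carbon mass conservation.

Generates everything the chamber system would have recorded: environmental
drivers, logistic plant growth, true hourly fluxes (heterotrophic and
autotrophic respiration, GPP, NEE), noisy 1 Hz chamber closure traces for the
chambered collars, DOC drainage events, and a final stock inventory whose
soil-carbon change is the exact mass-balance residual of the true fluxes —
so, before measurement noise, the stock balance equals the time-integrated
flux balance to machine precision.

Observation model for a closure trace:

    C(t) = C0 + m t + transient(t) + drawdown(t) + eps

where ``m`` is the ppm/s slope implied by the flux through the ideal-gas
conversion, ``transient`` is a mixing term active only in the first 20 s
(frozen at its end value afterwards, so the calculation window is untouched),
``drawdown`` is a decaying photosynthetic term in the first 50 s of opaque
daytime closures, and ``eps`` is white noise. The transparent lid transmits a
fraction ``tau`` of ambient PAR, so transparent-chamber photosynthesis (and
the recorded inside-PAR) sees ``tau * PAR``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .chamber import ChamberTrace, TraceSet, flux_to_concentration_slope
from .config import CARBON_MOLAR_MASS, R_GAS, SimConfig
from .environment import generate_environment, validate_environment

TRUTH_COLUMNS = ["collar_id", "timestamp", "shoot_dw", "root_dw",
                 "rhet", "rauto", "reco", "gpp", "nee", "nee_chamber"]

INVENTORY_COLUMNS = ["collar_id", "chamber", "nutrient", "d_c_soil",
                     "c_shoot", "c_root", "c_doc", "c_seed"]

DOC_COLUMNS = ["collar_id", "date", "volume_l", "conc_mg_l"]


def _collar_rng(config: SimConfig, group: int, collar_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(group, collar_index)))


def collar_table(config: SimConfig) -> pd.DataFrame:
    """The collar layout: 2x2 chamber x nutrient treatment labels plus
    per-collar growth multipliers (biological replicate variation).

    Collars are assigned to treatments in a repeating (+Ch+N, +Ch-N, -Ch+N,
    -Ch-N) cycle; per-collar random factors come from dedicated substreams so
    adding collars never perturbs existing ones.
    """
    rows = []
    n_chambered = round(config.n_collars * config.chambered_fraction)
    for i in range(config.n_collars):
        rng = _collar_rng(config, 1, i)
        growth = 1.0 + config.collar_growth_cv * rng.standard_normal()
        root_extra = 1.0 + config.root_extra_cv * rng.standard_normal()
        rhet = 1.0 + config.collar_rhet_cv * rng.standard_normal()
        rows.append({
            "collar_id": f"C{i + 1:02d}",
            "chamber": i < n_chambered,
            "nutrient": (i % 2) == 0,
            "growth_factor": max(growth, 0.1),
            "root_factor": max(growth * root_extra, 0.1),
            "rhet_factor": max(rhet, 0.1),
        })
    return pd.DataFrame(rows)


def shoot_dry_weight(config: SimConfig, timestamps: pd.DatetimeIndex,
                     growth_factor: float = 1.0) -> np.ndarray:
    """Logistic shoot dry weight (g): zero before germination, then a
    logistic rise towards the collar's final dry weight."""
    germ = dt.datetime.combine(config.germination_date, dt.time(0))
    days = (timestamps - pd.Timestamp(germ)) / pd.Timedelta(days=1)
    days = np.asarray(days, dtype=float)
    k = config.growth_rate_per_day
    mid = config.growth_midpoint_days
    s = special.expit(k * (days - mid))
    s[days < 0] = 0.0
    return config.final_shoot_dw_g * growth_factor * s


def gpp_potential(par: np.ndarray | float, config: SimConfig) -> np.ndarray:
    """Plateau light response a*ln(PAR)+c (umol m-2 s-1), clipped at zero
    below its zero-crossing and identically zero in the dark."""
    par = np.asarray(par, dtype=float)
    out = np.zeros_like(par)
    lit = par > 0
    with np.errstate(divide="ignore"):
        out[lit] = np.maximum(
            config.lr_coeff_a * np.log(par[lit]) + config.lr_coeff_c, 0.0)
    return out


def generate_true_fluxes(config: SimConfig, env: pd.DataFrame,
                         collars: pd.DataFrame | None = None) -> pd.DataFrame:
    """True hourly fluxes per collar (micromet sign, umol m-2 s-1).

    Heterotrophic respiration follows Rh0 * Q10_het^((T5cm - Tref)/10).
    Autotrophic respiration scales with shoot dry weight, follows Q10_auto on
    air temperature, and is suppressed by a constant factor whenever PAR > 0.
    GPP is the plateau light response scaled by shoot DW relative to final DW,
    at ambient PAR; ``nee = reco - gpp``. ``nee_chamber`` is what a transparent
    lid transmitting tau of ambient PAR would see.
    """
    validate_environment(env)
    temps = env[["t_air_c", "t_soil5_c"]].to_numpy()
    if not np.isfinite(temps).all():
        raise ValueError("non-finite temperature in environment")
    if (env["par"].to_numpy() < 0).any():
        raise ValueError("negative PAR in environment")
    if collars is None:
        collars = collar_table(config)
    ts = pd.to_datetime(env["timestamp"])
    t_air = env["t_air_c"].to_numpy()
    t_soil5 = env["t_soil5_c"].to_numpy()
    par = env["par"].to_numpy()

    rhet_base = config.rh0 * config.q10_het ** ((t_soil5 - config.tref_c) / 10.0)
    q_auto = config.q10_auto ** ((t_air - config.tref_c) / 10.0)
    supp = np.where(par > 0, config.suppression_s, 1.0)
    pot = gpp_potential(par, config)
    pot_chamber = gpp_potential(config.par_transmission * par, config)

    frames = []
    for row in collars.itertuples(index=False):
        rhet = rhet_base * getattr(row, "rhet_factor", 1.0)
        sdw = shoot_dry_weight(config, pd.DatetimeIndex(ts), row.growth_factor)
        rdw = sdw * (config.final_root_dw_g / config.final_shoot_dw_g) * (
            row.root_factor / row.growth_factor)
        rauto = config.r_auto_coeff * sdw * q_auto * supp
        scale = sdw / config.final_shoot_dw_g
        gpp = scale * pot
        reco = rhet + rauto
        nee = reco - gpp
        nee_chamber = reco - scale * pot_chamber
        frames.append(pd.DataFrame({
            "collar_id": row.collar_id, "timestamp": ts,
            "shoot_dw": sdw, "root_dw": rdw,
            "rhet": rhet, "rauto": rauto, "reco": reco,
            "gpp": gpp, "nee": nee, "nee_chamber": nee_chamber,
        }))
    return pd.concat(frames, ignore_index=True)


def synthesize_trace(flux: float, config: SimConfig, chamber_type: str,
                     rng: np.random.Generator, *, temperature_c: float = 10.0,
                     drawdown_flux: float = 0.0, par_out: float = 0.0,
                     collar_id: str = "C01", closure_id: str = "closure",
                     timestamp: dt.datetime | None = None) -> ChamberTrace:
    """Synthesise one closure :class:`ChamberTrace` encoding ``flux``.

    ``drawdown_flux`` (umol m-2 s-1, >= 0) activates the opaque daytime
    photosynthetic drawdown term: photosynthesis at that rate decays with the
    configured time constant over the first 50 s after darkening. The
    transparent chamber's inside PAR is recorded as tau * par_out (plus
    configured sensor noise).
    """
    if chamber_type not in ("transparent", "opaque"):
        raise ValueError(f"unknown chamber type {chamber_type!r}")
    if not math.isfinite(flux):
        raise ValueError("flux must be finite")
    if config.trace_duration_s <= 0:
        raise ValueError("trace duration must be positive")
    t = np.arange(config.trace_duration_s, dtype=float)
    m = flux_to_concentration_slope(
        flux, config.chamber_volume_m3, config.collar_area_m2,
        temperature_c + 273.15, config.pressure_pa)
    co2 = config.baseline_co2_ppm + m * t

    if config.transient_amp_ppm != 0.0:
        tt = np.minimum(t, config.transient_cutoff_s)
        co2 = co2 + config.transient_amp_ppm * np.exp(-tt / config.transient_tau_s)

    if chamber_type == "opaque" and drawdown_flux > 0.0:
        m_gpp = flux_to_concentration_slope(
            drawdown_flux, config.chamber_volume_m3, config.collar_area_m2,
            temperature_c + 273.15, config.pressure_pa)
        td = np.minimum(t, config.drawdown_cutoff_s)
        co2 = co2 - m_gpp * config.drawdown_tau_s * (
            1.0 - np.exp(-td / config.drawdown_tau_s))

    if config.trace_noise_sd_ppm > 0:
        co2 = co2 + rng.normal(0.0, config.trace_noise_sd_ppm, size=t.size)

    if chamber_type == "transparent":
        par_in = config.par_transmission * par_out
        if config.par_sensor_cv > 0:
            par_in = max(par_in * (1.0 + config.par_sensor_cv
                                   * rng.standard_normal()), 0.0)
    else:
        par_in = 0.0
    return ChamberTrace(
        closure_id=closure_id, collar_id=collar_id, chamber_type=chamber_type,
        timestamp=timestamp or dt.datetime(2006, 11, 1),
        t=t, co2=co2, volume_m3=config.chamber_volume_m3,
        area_m2=config.collar_area_m2, t_air_c=temperature_c,
        pressure_pa=config.pressure_pa, par_in=par_in, par_out=par_out)


def generate_traces(config: SimConfig, env: pd.DataFrame, truth: pd.DataFrame,
                    collars: pd.DataFrame) -> TraceSet:
    """Closure traces for every chambered collar: an opaque closure every hour
    of the run, and a transparent closure from the post-sowing stage onward,
    the transparent one preceding the opaque one inside each hour (as in the
    multiplexer cycle)."""
    ts = pd.to_datetime(env["timestamp"])
    par = env["par"].to_numpy()
    t_air = env["t_air_c"].to_numpy()
    tau = config.par_transmission
    t_axis = np.arange(config.trace_duration_s, dtype=float)
    transparent_from = pd.Timestamp(
        dt.datetime.combine(config.s2_start, dt.time(0)))

    metas = []
    blocks = []
    chambered = collars[collars["chamber"]].reset_index(drop=True)
    for rank, row in enumerate(chambered.itertuples(index=False)):
        rng = _collar_rng(config, 4, rank)
        tr = truth[truth["collar_id"] == row.collar_id]
        tr = tr.set_index(pd.to_datetime(tr["timestamp"]))
        reco = tr["reco"].to_numpy()
        nee_ch = tr["nee_chamber"].to_numpy()
        gpp = tr["gpp"].to_numpy()
        n_h = len(ts)
        # multiplexer cycle: all closures of one hour must finish inside it
        step_s = min(340, 3200 // max(len(chambered), 1))
        offset = pd.Timedelta(seconds=step_s * rank)

        for ctype, fluxes in (("transparent", nee_ch), ("opaque", reco)):
            if ctype == "transparent":
                active = (ts >= transparent_from).to_numpy()
            else:
                active = np.ones(n_h, dtype=bool)
            idx = np.flatnonzero(active)
            k = idx.size
            t_k = t_air[idx] + 273.15
            m = fluxes[idx] * (R_GAS * t_k * config.collar_area_m2) / (
                config.pressure_pa * config.chamber_volume_m3)
            co2 = config.baseline_co2_ppm + np.outer(m, t_axis)
            if config.transient_amp_ppm != 0.0:
                tt = np.minimum(t_axis, config.transient_cutoff_s)
                co2 += config.transient_amp_ppm * np.exp(-tt / config.transient_tau_s)
            if ctype == "opaque":
                day = par[idx] > 0
                if day.any():
                    m_gpp = gpp[idx[day]] * (R_GAS * t_k[day] * config.collar_area_m2) / (
                        config.pressure_pa * config.chamber_volume_m3)
                    td = np.minimum(t_axis, config.drawdown_cutoff_s)
                    shape = 1.0 - np.exp(-td / config.drawdown_tau_s)
                    co2[day] -= config.drawdown_tau_s * np.outer(m_gpp, shape)
            if config.trace_noise_sd_ppm > 0:
                co2 += rng.normal(0.0, config.trace_noise_sd_ppm, size=co2.shape)

            if ctype == "transparent":
                par_in = tau * par[idx]
                if config.par_sensor_cv > 0:
                    par_in = par_in * (1.0 + config.par_sensor_cv
                                       * rng.standard_normal(k))
                    par_in = np.maximum(par_in, 0.0)
                t_extra = pd.Timedelta(0)
            else:
                par_in = np.zeros(k)
                t_extra = pd.Timedelta(seconds=170)
            stamp = ts.iloc[idx] + offset + t_extra
            tag = "T" if ctype == "transparent" else "O"
            metas.append(pd.DataFrame({
                "closure_id": [f"{row.collar_id}-{h:%Y%m%d%H}-{tag}"
                               for h in ts.iloc[idx]],
                "collar_id": row.collar_id,
                "chamber_type": ctype,
                "timestamp": stamp.to_numpy(),
                "volume_m3": config.chamber_volume_m3,
                "area_m2": config.collar_area_m2,
                "t_air_c": t_air[idx],
                "pressure_pa": config.pressure_pa,
                "par_in": par_in,
                "par_out": par[idx],
            }))
            blocks.append(co2)

    meta = pd.concat(metas, ignore_index=True)
    co2_all = np.vstack(blocks)
    order = np.argsort(meta["timestamp"].to_numpy(), kind="stable")
    meta = meta.iloc[order].reset_index(drop=True)
    return TraceSet(meta=meta, t=t_axis, co2=co2_all[order])


def generate_doc_events(config: SimConfig, env: pd.DataFrame,
                        collars: pd.DataFrame | None = None) -> pd.DataFrame:
    """DOC drainage collection events per collar.

    Rainfall (shared across collars) accumulates in each collar's drainage
    bottle scaled by the capture efficiency; the bottle is emptied after wet
    spells once it holds more than the collection threshold, plus a final
    collection at the end of the run. Concentrations are drawn per event
    around the configured mean. Zero rain hours means zero events.
    """
    if collars is None:
        collars = collar_table(config)
    rain = env["rain"].to_numpy(dtype=bool)
    ts = pd.to_datetime(env["timestamp"])
    rng_rain = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(5,)))
    amounts_mm = np.where(rain, rng_rain.exponential(
        config.rain_mean_mm_per_h, size=rain.size), 0.0)
    litres = amounts_mm * config.collar_area_m2 * config.doc_capture_efficiency

    # collection times are shared: bottle level driven by shared rainfall
    level = 0.0
    collect_at: list[tuple[int, float]] = []
    for i in range(len(rain)):
        level += litres[i]
        dry_tail = not rain[max(0, i - 5):i + 1].any()
        if level >= config.doc_collect_threshold_l and dry_tail:
            collect_at.append((i, level))
            level = 0.0
    if level > 0.05:
        collect_at.append((len(rain) - 1, level))

    rows = []
    for ci, row in enumerate(collars.itertuples(index=False)):
        rng = _collar_rng(config, 2, ci)
        for i, vol in collect_at:
            conc = config.doc_conc_mg_l
            if config.doc_conc_sd_mg_l > 0:
                conc = max(0.0, rng.normal(conc, config.doc_conc_sd_mg_l))
            rows.append({"collar_id": row.collar_id, "date": ts.iloc[i].date(),
                         "volume_l": vol, "conc_mg_l": conc})
    return pd.DataFrame(rows, columns=DOC_COLUMNS)


class ConservationError(RuntimeError):
    """Internal mass-balance violation in the simulator."""


def generate_stock_inventory(config: SimConfig, truth: pd.DataFrame,
                             doc_events: pd.DataFrame,
                             collars: pd.DataFrame | None = None) -> pd.DataFrame:
    """Final stock inventory per collar with enforced mass conservation.

    Shoot, root and seed pools come from simulated biomass and carbon
    fractions; the soil-carbon change is the exact conservation residual

        dC_soil = C_seed - integral(NEE) - C_DOC - C_shoot - C_root,

    so before measurement noise the Eq.-style stock balance equals the
    integrated flux balance identically. Configured measurement noise is then
    added per pool.
    """
    if collars is None:
        collars = collar_table(config)
    hours_factor = 3600.0 * CARBON_MOLAR_MASS * 1e-6 * config.collar_area_m2
    doc_c = doc_events.assign(
        g=lambda d: d["volume_l"] * d["conc_mg_l"] * 1e-3).groupby(
        "collar_id")["g"].sum()

    rows = []
    for ci, row in enumerate(collars.itertuples(index=False)):
        tr = truth[truth["collar_id"] == row.collar_id]
        flux_c = float(tr["nee"].sum()) * hours_factor
        c_shoot = float(tr["shoot_dw"].iloc[-1]) * config.c_frac_shoot
        c_root = float(tr["root_dw"].iloc[-1]) * config.c_frac_root
        c_seed = config.seed_dw_g * config.c_frac_seed
        c_doc = float(doc_c.get(row.collar_id, 0.0))
        d_c_soil = c_seed - flux_c - c_doc - c_shoot - c_root
        residual = -(d_c_soil + c_shoot + c_root + c_doc - c_seed) - flux_c
        if abs(residual) > 1e-9:
            raise ConservationError(
                f"collar {row.collar_id}: conservation residual {residual:.3e} g")
        rng = _collar_rng(config, 3, ci)
        rows.append({
            "collar_id": row.collar_id,
            "chamber": row.chamber, "nutrient": row.nutrient,
            "d_c_soil": d_c_soil + rng.normal(0, config.stock_noise_soil_g)
            if config.stock_noise_soil_g else d_c_soil,
            "c_shoot": c_shoot + rng.normal(0, config.stock_noise_shoot_g)
            if config.stock_noise_shoot_g else c_shoot,
            "c_root": c_root + rng.normal(0, config.stock_noise_root_g)
            if config.stock_noise_root_g else c_root,
            "c_doc": max(c_doc + rng.normal(0, config.stock_noise_doc_g), 0.0)
            if config.stock_noise_doc_g else c_doc,
            "c_seed": c_seed + rng.normal(0, config.stock_noise_seed_g)
            if config.stock_noise_seed_g else c_seed,
        })
    return pd.DataFrame(rows, columns=INVENTORY_COLUMNS)


@dataclass
class SimulationResult:
    """Everything one simulated campaign produced."""

    config: SimConfig
    env: pd.DataFrame
    collars: pd.DataFrame
    truth: pd.DataFrame
    traces: TraceSet
    doc_events: pd.DataFrame
    inventory: pd.DataFrame


def simulate_mesocosm(config: SimConfig | None = None,
                      with_traces: bool = True) -> SimulationResult:
    """Run the full forward simulation for one campaign."""
    config = config or SimConfig()
    env = generate_environment(config)
    collars = collar_table(config)
    truth = generate_true_fluxes(config, env, collars)
    traces = generate_traces(config, env, truth, collars) if with_traces else None
    doc_events = generate_doc_events(config, env, collars)
    inventory = generate_stock_inventory(config, truth, doc_events, collars)
    return SimulationResult(config=config, env=env, collars=collars,
                            truth=truth, traces=traces,
                            doc_events=doc_events, inventory=inventory)
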