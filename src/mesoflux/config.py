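"""Configuration objects for the simulator and the processing pipeline.

Two dataclasses carry all tunables: :class:`SimConfig` parameterises the
forward mesocosm simulator (study design, environment, physiology, observation
noise) and :class:`RunConfig` parameterises the processing pipeline (dead
bands, QC thresholds, correction policy, budget integration). Both round-trip
through flat YAML mappings and hash stably for run manifests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

R_GAS = 8.314  # J mol-1 K-1
CARBON_MOLAR_MASS = 12.011  # g mol-1


def _as_date(value: Any) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class StageWindows:
    """Four contiguous developmental-stage date intervals (inclusive dates).

    S1 bare soil, S2 germination, S3 seedling, S4 established plants. A
    boundary date belongs to the later stage's start, with inclusive day ranges.
    """

    s1_start: dt.date
    s2_start: dt.date
    s3_start: dt.date
    s4_start: dt.date
    end: dt.date

    LABELS = ("S1", "S2", "S3", "S4")

    def __post_init__(self) -> None:
        seq = [self.s1_start, self.s2_start, self.s3_start, self.s4_start, self.end]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("stage boundaries must be strictly increasing")

    def label(self, when: dt.date | dt.datetime) -> str:
        d = _as_date(when)
        if d < self.s1_start or d > self.end:
            raise ValueError(f"timestamp {d} outside stage windows")
        if d >= self.s4_start:
            return "S4"
        if d >= self.s3_start:
            return "S3"
        if d >= self.s2_start:
            return "S2"
        return "S1"

    def bounds(self, label: str) -> tuple[dt.date, dt.date]:
        starts = {
            "S1": (self.s1_start, self.s2_start - dt.timedelta(days=1)),
            "S2": (self.s2_start, self.s3_start - dt.timedelta(days=1)),
            "S3": (self.s3_start, self.s4_start - dt.timedelta(days=1)),
            "S4": (self.s4_start, self.end),
        }
        if label not in starts:
            raise KeyError(f"unknown stage label {label!r}")
        return starts[label]


@dataclass
class SimConfig:
    """Parameters of the synthetic mesocosm experiment.

    Defaults reproduce the reference campaign layout: 12 mesocosm collars in a 2x2
    chamber x nutrient design (3 replicates each, chambers on the +Ch half),
    run from 31 Oct 2006 to 23 Jan 2007 with hourly paired
    transparent/opaque closures, ~34% PAR attenuation under the transparent
    lid, and pool magnitudes near the reference inventory (seed C ~1.3 g,
    shoot+root C ~1.5 g, small soil-C change).
    """

    # --- experiment layout ---
    start_date: dt.date = dt.date(2006, 10, 31)
    end_date: dt.date = dt.date(2007, 1, 23)
    sowing_date: dt.date = dt.date(2006, 11, 3)
    germination_date: dt.date = dt.date(2006, 11, 14)
    n_collars: int = 12
    chambered_fraction: float = 0.5  # +Ch half of the 2x2 design
    collar_area_m2: float = 0.0278
    chamber_volume_m3: float = 0.004823
    pressure_pa: float = 101325.0

    # stage windows (S2 start = day after sowing monitoring switch)
    s2_start: dt.date = dt.date(2006, 11, 4)
    s3_start: dt.date = dt.date(2006, 11, 14)
    s4_start: dt.date = dt.date(2006, 11, 28)

    # --- environment generator ---
    latitude_deg: float = 54.0
    t_mean_start_c: float = 8.0
    t_mean_end_c: float = 2.0
    diurnal_amp_c: float = 3.0
    temp_ar1_rho: float = 0.8
    temp_noise_sd_c: float = 1.2
    par_peak_coeff: float = 1800.0  # clear-sky noon PAR = coeff * cos(lat - declination)
    cloud_min: float = 0.25
    cloud_max: float = 1.0
    par_lognorm_sigma: float = 0.15
    rain_p_wet_given_wet: float = 0.85
    rain_p_wet_given_dry: float = 0.04
    rain_mean_mm_per_h: float = 0.5

    # --- physiology / true fluxes ---
    rh0: float = 0.11  # umol m-2 s-1 heterotrophic respiration at Tref
    q10_het: float = 2.45
    q10_auto: float = 2.5
    tref_c: float = 10.0
    r_auto_coeff: float = 0.28  # umol m-2 s-1 per g shoot DW at Tref
    suppression_s: float = 0.8  # daytime multiplier on autotrophic respiration
    lr_coeff_a: float = 0.39  # GPP = scale * (a*ln(PAR) + c), clipped at 0
    lr_coeff_c: float = -0.21
    par_transmission: float = 0.66  # lid transmission tau

    # --- growth ---
    final_shoot_dw_g: float = 1.75
    final_root_dw_g: float = 2.43
    seed_dw_g: float = 3.13
    growth_rate_per_day: float = 1.2  # bulk germination: abrupt establishment
    growth_midpoint_days: float = 7.0  # days after germination
    collar_growth_cv: float = 0.05
    root_extra_cv: float = 0.05
    collar_rhet_cv: float = 0.35  # replicate soil-respiration variability

    # --- carbon fractions (mass fraction of dry weight) ---
    c_frac_seed: float = 0.415
    c_frac_shoot: float = 0.405
    c_frac_root: float = 0.345
    c_frac_soil: float = 0.005
    soil_mass_g: float = 2500.0

    # --- DOC ---
    doc_conc_mg_l: float = 20.0
    doc_conc_sd_mg_l: float = 1.0
    doc_capture_efficiency: float = 0.55
    doc_collect_threshold_l: float = 0.6

    # --- chamber observation model ---
    baseline_co2_ppm: float = 400.0
    trace_noise_sd_ppm: float = 0.3
    trace_duration_s: int = 145
    transient_amp_ppm: float = 5.0
    transient_tau_s: float = 10.0
    transient_cutoff_s: float = 20.0
    drawdown_tau_s: float = 15.0
    drawdown_cutoff_s: float = 50.0
    par_sensor_cv: float = 0.02

    # --- stock measurement noise (g C, 1 sd) ---
    stock_noise_soil_g: float = 0.005
    stock_noise_shoot_g: float = 0.003
    stock_noise_root_g: float = 0.005
    stock_noise_doc_g: float = 0.0005
    stock_noise_seed_g: float = 0.0005

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("start_date", "end_date", "sowing_date", "germination_date",
                     "s2_start", "s3_start", "s4_start"):
            object.__setattr__(self, name, _as_date(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        if not (0.0 < self.par_transmission <= 1.0):
            raise ValueError("par_transmission must be in (0, 1]")
        for name in ("q10_het", "q10_auto"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c_frac_seed", "c_frac_shoot", "c_frac_root", "c_frac_soil"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0.0 < self.suppression_s <= 1.0):
            raise ValueError("suppression_s must be in (0, 1]")
        if self.n_collars < 1:
            raise ValueError("n_collars must be >= 1")
        if self.collar_area_m2 <= 0 or self.chamber_volume_m3 <= 0:
            raise ValueError("geometry must be positive")
        if self.trace_duration_s <= 0:
            raise ValueError("trace_duration_s must be positive")
        # stage windows validate themselves
        _ = self.stage_windows

    @property
    def stage_windows(self) -> StageWindows:
        return StageWindows(self.start_date, self.s2_start, self.s3_start,
                            self.s4_start, self.end_date)

    def ideal(self) -> "SimConfig":
        """Ideal-chamber variant: no measurement noise and a fully
        transmitting lid, so observed fluxes equal true fluxes exactly.
        Used for accounting-chain closure checks."""
        return dataclasses.replace(
            self,
            par_transmission=1.0,
            trace_noise_sd_ppm=0.0,
            par_sensor_cv=0.0,
            doc_conc_sd_mg_l=0.0,
            stock_noise_soil_g=0.0,
            stock_noise_shoot_g=0.0,
            stock_noise_root_g=0.0,
            stock_noise_doc_g=0.0,
            stock_noise_seed_g=0.0,
        )

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, dt.date):
                out[k] = v.isoformat()
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunConfig:
    """Processing-pipeline parameters (flux fitting, QC, correction, budget)."""

    sim: SimConfig = field(default_factory=SimConfig)

    # chamber_flux
    deadband_transparent_s: float = 20.0
    deadband_opaque_s: float = 50.0
    window_s: float = 90.0
    night_par_threshold: float = 5.0  # umol m-2 s-1
    r2_threshold: float = 0.75
    slope_noise_floor_ppm_s: float = 0.005

    # par_correction
    light_response_form: str = "log"  # or "hyperbola"
    light_response_scope: str = "collar"  # per-collar fits; "plot" = one model
    correction_onset: dt.date = dt.date(2006, 11, 21)
    # the log-form offset is PAR-independent, so every lit record suffers it;
    # restricting to bright hours leaves dawn/dusk losses uncorrected
    correction_par_threshold: float = 0.0
    fit_window_start: dt.date = dt.date(2006, 12, 1)
    min_light_response_points: int = 20
    use_par_in: bool = True  # correct from measured par_in; else par_out * tau

    # budget
    presowing_reco_as_nee: bool = True
    gap_fill_max_h: int = 3
    min_coverage: float = 0.95

    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "correction_onset", _as_date(self.correction_onset))
        object.__setattr__(self, "fit_window_start", _as_date(self.fit_window_start))
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.light_response_form not in ("log", "hyperbola"):
            raise ValueError("light_response_form must be 'log' or 'hyperbola'")
        if self.light_response_scope not in ("collar", "plot"):
            raise ValueError("light_response_scope must be 'collar' or 'plot'")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["sim"] = self.sim.to_dict()
        for k, v in out.items():
            if isinstance(v, dt.date):
                out[k] = v.isoformat()
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        sim = data.pop("sim", {})
        if isinstance(sim, dict):
            sim = SimConfig.from_dict(sim)
        names = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(sim=sim, **data)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig | SimConfig) -> str:
    """Stable hash of the semantic config content (order-independent)."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]
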