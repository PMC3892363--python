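"""Pipeline driver: simulate -> flux -> correct -> q10 -> budget -> validate.

Each stage is a pure function from input frames to output frames; the
file-based runner wires them through the CSV dialects in ``io`` so stages can
be re-run individually, writes a run manifest, and never mutates its inputs.
The same stage functions are importable for in-memory use (see
:func:`analyze`), which is how the examples and the validation experiments
drive the package.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .budget import budgets_frame, collar_budget, compare_balances
from .chamber import TraceSet, fit_traces, qc_filter
from .config import RunConfig, config_hash
from .light import (LightResponseModel, apply_correction, fit_attenuation,
                    fit_light_response, usable_daytime_transparent)
from .respiration import (day_night_suppression, fit_q10_by_stage,
                          partition_gpp, q10_fits_frame,
                          select_temperature_driver, segment_stages)
from .simulate import SimulationResult, simulate_mesocosm

log = logging.getLogger("mesoflux")

STAGES = ("simulate", "flux", "correct", "q10", "budget", "validate")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stage functions (in-memory)


def stage_flux(traces: TraceSet, env: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    records = fit_traces(traces, config)
    return qc_filter(records, env,
                     night_par_threshold=config.night_par_threshold,
                     r2_threshold=config.r2_threshold,
                     slope_noise_floor_ppm_s=config.slope_noise_floor_ppm_s)


def stage_correct(records: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Estimate lid transmission, fit the light response, correct daytime NEE.

    The light response is fitted on the configured window (default the
    established-plant period); with ``light_response_scope='collar'`` each
    collar gets its own fit so the correction scales with replicate
    photosynthetic amplitude (the pooled plot-level model is the fallback,
    and the only model when scope is 'plot' — the single-PAR-sensor case).
    """
    day_tr = usable_daytime_transparent(records)
    att = fit_attenuation(day_tr["par_out"].to_numpy(dtype=float),
                          day_tr["par_in"].to_numpy(dtype=float))
    fit_set = usable_daytime_transparent(records, config.fit_window_start)
    plot_model = fit_light_response(fit_set, form=config.light_response_form,
                                    min_points=config.min_light_response_points)
    model: LightResponseModel | dict[str, LightResponseModel]
    per_collar: dict[str, LightResponseModel] = {}
    if config.light_response_scope == "collar":
        for cid, sub in fit_set.groupby("collar_id"):
            try:
                per_collar[cid] = fit_light_response(
                    sub, form=config.light_response_form,
                    min_points=config.min_light_response_points)
            except ValueError:
                per_collar[cid] = plot_model
        model = per_collar
    else:
        model = plot_model
    corrected = apply_correction(records, model, att.transmission,
                                 config.correction_onset, config,
                                 fallback=plot_model)
    report = {
        "transmission": att.transmission, "attenuation": att.attenuation,
        "attenuation_r2": att.r2, "attenuation_n": att.n,
        "form": plot_model.form, "coefficients": list(plot_model.coeffs),
        "r2": plot_model.r2, "n": plot_model.n,
        "par_domain": list(plot_model.par_domain),
        "scope": config.light_response_scope,
        "per_collar_a": {k: m.coeffs[0] for k, m in per_collar.items()},
        "n_corrected": int(corrected["corrected_flag"].sum()),
    }
    return corrected, report


def stage_q10(records: pd.DataFrame, env: pd.DataFrame,
              config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Stage-wise Q10 fits, hourly GPP partition, and the suppression estimate.

    Temperature-driver selection follows the monitored design: the bare-soil
    stage is screened against soil temperatures, later stages against chamber
    air temperature, with ln(Reco)-temperature correlation deciding.
    """
    windows = config.sim.stage_windows
    opaque = records[(records["chamber_type"] == "opaque")
                     & np.isfinite(records["flux"])].copy()
    labelled = segment_stages(opaque, windows)

    env_idx = env.set_index(pd.to_datetime(env["timestamp"]))
    hours = pd.to_datetime(labelled["timestamp"]).dt.floor("h")
    for cand in ("t_surf_c", "t_soil2_c", "t_soil5_c"):
        labelled[cand] = hours.map(env_idx[cand]).to_numpy(dtype=float)

    drivers: dict[str, str] = {}
    s1 = labelled[labelled["stage"] == "S1"]
    if len(s1) >= 20:
        best, _ = select_temperature_driver(
            s1, env, candidates=("temperature_c", "t_surf_c", "t_soil2_c",
                                 "t_soil5_c"))
        drivers["S1"] = best
    post = labelled[labelled["stage"] != "S1"]
    if len(post) >= 20:
        best, _ = select_temperature_driver(
            post, env, candidates=("temperature_c", "t_surf_c", "t_soil2_c",
                                   "t_soil5_c"))
        for s in ("S2", "S3", "S4"):
            drivers[s] = best

    fits = []
    for stage in windows.LABELS:
        sub = labelled[labelled["stage"] == stage]
        var = drivers.get(stage, "temperature_c")
        try:
            from .respiration import fit_q10
            fits.append(fit_q10(sub, var, stage=stage))
        except ValueError:
            continue
    q10_frame = q10_fits_frame(fits)

    post_germ = labelled[labelled["stage"].isin(("S3", "S4"))]
    suppression = None
    try:
        est = day_night_suppression(post_germ)
        suppression = {"ratio": est.ratio, "se_ratio": est.se_ratio,
                       "n_day": est.n_day, "n_night": est.n_night}
    except ValueError:
        pass

    pairs = _hourly_pairs(records)
    paired = pairs.dropna(subset=["nee", "reco"])
    gpp = partition_gpp(paired, config.night_par_threshold)
    info = {"drivers": drivers, "suppression": suppression,
            "n_gpp_hours": int(len(gpp)),
            "n_gpp_clipped": int(gpp["clipped"].sum())}
    return q10_frame, gpp, info


def _hourly_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Collar-hour frame with nee (corrected transparent flux when present)
    and reco (opaque flux)."""
    rec = records.copy()
    rec["hour"] = pd.to_datetime(rec["timestamp"]).dt.floor("h")
    flux_col = "flux_corrected" if "flux_corrected" in rec.columns else "flux"
    tr = rec[rec["chamber_type"] == "transparent"]
    op = rec[rec["chamber_type"] == "opaque"]
    nee = tr.set_index(["collar_id", "hour"])[flux_col]
    reco = op.set_index(["collar_id", "hour"])["flux"]
    out = pd.concat({"nee": nee, "reco": reco}, axis=1).reset_index()
    meta = pd.concat([op, tr]).drop_duplicates(["collar_id", "hour"])
    out = out.merge(meta[["collar_id", "hour", "par_out", "temperature_c"]],
                    on=["collar_id", "hour"], how="left")
    return out.rename(columns={"hour": "timestamp"})


def stage_budget(records: pd.DataFrame, doc_events: pd.DataFrame,
                 inventory: pd.DataFrame, env: pd.DataFrame,
                 config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Per-collar budgets plus the ensemble comparison report.

    The hourly NEE series per collar uses corrected transparent fluxes;
    before the transparent chambers started (bare soil, no photosynthesis)
    the opaque flux stands in for NEE when the policy flag allows.
    """
    pairs = _hourly_pairs(records)
    full_hours = pd.DatetimeIndex(pd.to_datetime(env["timestamp"]))
    s2 = pd.Timestamp(dt.datetime.combine(config.sim.s2_start, dt.time(0)))
    budgets = []
    for collar_id, sub in pairs.groupby("collar_id"):
        series = sub.set_index("timestamp")["nee"].reindex(full_hours)
        if config.presowing_reco_as_nee:
            reco = sub.set_index("timestamp")["reco"].reindex(full_hours)
            pre = full_hours < s2
            series[pre] = series[pre].fillna(reco[pre])
        inv_rows = inventory[inventory["collar_id"] == collar_id]
        if inv_rows.empty:
            continue
        doc = doc_events[doc_events["collar_id"] == collar_id]
        budgets.append(collar_budget(
            collar_id, series.to_numpy(), inv_rows.iloc[0], doc,
            config.sim.collar_area_m2, expected_hours=len(full_hours),
            min_coverage=config.min_coverage,
            gap_fill_max_h=config.gap_fill_max_h))
    frame = budgets_frame(budgets)
    report: dict = {}
    if len(frame) >= 2:
        try:
            report = compare_balances(frame, grouping="nutrient")
        except ValueError:
            # singleton treatment groups: fall back to the ungrouped report
            report = compare_balances(frame, grouping=None)
    return frame, report


def stage_validate(budgets: pd.DataFrame, tolerance_g: float = 1e-6) -> dict:
    """Closure check: |flux - stock| per collar against a tolerance, plus the
    ensemble criterion (within 2 pooled SD)."""
    diff = (budgets["flux_balance"] - budgets["stock_balance"]).to_numpy(float)
    pooled_sd = float(np.sqrt(0.5 * (budgets["flux_balance"].std(ddof=1) ** 2
                                     + budgets["stock_balance"].std(ddof=1) ** 2)))
    per_collar = {
        cid: {"difference": float(d), "within_tolerance": bool(abs(d) < tolerance_g)}
        for cid, d in zip(budgets["collar_id"], diff)}
    return {
        "tolerance_g": tolerance_g,
        "per_collar": per_collar,
        "all_within_tolerance": bool(np.all(np.abs(diff) < tolerance_g)),
        "max_abs_difference": float(np.max(np.abs(diff))),
        "pooled_sd": pooled_sd,
        "all_within_2sd": bool(np.all(np.abs(diff) < 2 * pooled_sd))
        if pooled_sd > 0 else True,
    }


# ---------------------------------------------------------------------------
# in-memory end-to-end


@dataclass
class AnalysisResult:
    records: pd.DataFrame  # corrected flux records
    correction_report: dict
    q10_fits: pd.DataFrame
    gpp: pd.DataFrame
    q10_info: dict
    budgets: pd.DataFrame
    comparison: dict
    validation: dict


def analyze(sim: SimulationResult, config: RunConfig | None = None,
            closure_tolerance_g: float = 1e-6) -> AnalysisResult:
    """Run the full processing chain on a simulation, in memory."""
    config = config or RunConfig(sim=sim.config)
    if config.sim is not sim.config:
        config = dataclasses.replace(config, sim=sim.config)
    records = stage_flux(sim.traces, sim.env, config)
    corrected, report = stage_correct(records, config)
    q10_frame, gpp, info = stage_q10(corrected, sim.env, config)
    budgets, comparison = stage_budget(corrected, sim.doc_events,
                                       sim.inventory, sim.env, config)
    validation = stage_validate(budgets, closure_tolerance_g)
    return AnalysisResult(records=corrected, correction_report=report,
                          q10_fits=q10_frame, gpp=gpp, q10_info=info,
                          budgets=budgets, comparison=comparison,
                          validation=validation)


# ---------------------------------------------------------------------------
# file-based runner


def _artifact(outdir: Path, name: str) -> Path:
    return outdir / name


def run_pipeline(config: RunConfig, stages: list[str] | None = None,
                 outdir: str | Path = ".", seed: int | None = None) -> dict:
    """Execute the requested pipeline stages against CSV artifacts in
    ``outdir``; returns the manifest dict. Raises :class:`StageError` naming
    the failing stage; partial outputs gain a ``.partial`` marker file."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise StageError(unknown.pop(), "unknown stage")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(
            config, sim=dataclasses.replace(config.sim, rng_seed=seed))
    rows: dict[str, int] = {}

    def need(name: str, stage: str) -> Path:
        p = _artifact(outdir, name)
        if not p.exists():
            raise StageError(stage, f"missing input file {p}")
        return p

    for stage in STAGES:
        if stage not in stages:
            continue
        marker = outdir / f"{stage}.partial"
        marker.write_text("running\n")
        try:
            if stage == "simulate":
                sim = simulate_mesocosm(config.sim)
                mio.write_csv(sim.env, outdir / "env.csv", "env")
                mio.write_csv(sim.traces.to_long_frame(),
                              outdir / "traces.csv", "traces")
                mio.write_csv(sim.doc_events.assign(
                    date=lambda d: d["date"].astype(str)),
                    outdir / "doc.csv", "doc")
                mio.write_csv(sim.inventory, outdir / "inventory.csv", "inventory")
                mio.write_csv(sim.truth, outdir / "truth.csv", "truth")
                rows["traces.csv"] = len(sim.traces.meta)
                rows["env.csv"] = len(sim.env)
            elif stage == "flux":
                traces = TraceSet.from_long_frame(
                    mio.read_csv(need("traces.csv", stage), "traces"))
                env = mio.read_csv(need("env.csv", stage), "env")
                records = stage_flux(traces, env, config)
                mio.write_csv(records, outdir / "fluxes.csv", "fluxes")
                rows["fluxes.csv"] = len(records)
            elif stage == "correct":
                records = mio.read_csv(need("fluxes.csv", stage), "fluxes")
                corrected, report = stage_correct(records, config)
                mio.write_csv(corrected, outdir / "fluxes_corrected.csv",
                              "fluxes_corrected")
                (outdir / "light_response.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True) + "\n")
                rows["fluxes_corrected.csv"] = len(corrected)
            elif stage == "q10":
                records = mio.read_csv(
                    need("fluxes_corrected.csv", stage), "fluxes_corrected")
                env = mio.read_csv(need("env.csv", stage), "env")
                q10_frame, gpp, info = stage_q10(records, env, config)
                q10_frame.to_csv(outdir / "q10_fits.csv", index=False,
                                 lineterminator="\n")
                gpp.to_csv(outdir / "gpp.csv", index=False, lineterminator="\n")
                (outdir / "q10_info.json").write_text(
                    json.dumps(info, indent=2, sort_keys=True) + "\n")
                rows["q10_fits.csv"] = len(q10_frame)
            elif stage == "budget":
                records = mio.read_csv(
                    need("fluxes_corrected.csv", stage), "fluxes_corrected")
                doc = mio.read_csv(need("doc.csv", stage), "doc")
                inventory = mio.read_csv(need("inventory.csv", stage), "inventory")
                env = mio.read_csv(need("env.csv", stage), "env")
                budgets, report = stage_budget(records, doc, inventory, env, config)
                mio.write_csv(budgets, outdir / "budgets.csv", "budgets")
                (outdir / "comparison.txt").write_text(
                    _format_comparison(report))
                rows["budgets.csv"] = len(budgets)
            elif stage == "validate":
                budgets = mio.read_csv(need("budgets.csv", stage), "budgets")
                result = stage_validate(budgets)
                (outdir / "closure_report.json").write_text(
                    json.dumps(result, indent=2, sort_keys=True) + "\n")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(stage, str(exc)) from exc
        marker.unlink(missing_ok=True)

    manifest = {"config_hash": config_hash(config),
                "seed": config.sim.rng_seed, "artifact_rows": rows}
    mio.write_manifest(outdir / "manifest.json",
                       config_hash=manifest["config_hash"],
                       seed=manifest["seed"], artifacts=rows)
    return manifest


def _format_comparison(report: dict) -> str:
    if not report:
        return "no comparison (fewer than 2 budgets)\n"
    lines = [
        "Flux- vs stock-based carbon balances (g C per mesocosm)",
        f"n = {report['n']}",
        f"mean difference (flux - stock): {report['mean_difference']:.4f} "
        f"+- {report['sd_difference']:.4f}",
        f"paired t = {report['paired_t']:.3f} (p = {report['paired_p']:.3f})",
        f"RMSE about 1:1 line: {report['rmse_1to1']:.4f}",
        f"OLS flux~stock: slope {report['slope']:.3f}, "
        f"intercept {report['intercept']:.4f}",
        f"flux balance: {report['flux_mean']:.3f} +- {report['flux_sd']:.3f}",
        f"stock balance: {report['stock_mean']:.3f} +- {report['stock_sd']:.3f}",
    ]
    for key in ("anova_flux_balance", "anova_stock_balance"):
        if key in report:
            lines.append(f"{key}: F = {report[key]['F']:.3f}, "
                         f"p = {report[key]['p']:.3f}")
    if "group_means" in report:
        for g, v in report["group_means"].items():
            lines.append(
                f"group {g} (n={v['n']}): flux {v['flux']:.3f} +- "
                f"{v['flux_sd']:.3f}, stock {v['stock']:.3f} +- {v['stock_sd']:.3f}")
    return "\n".join(lines) + "\n"
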