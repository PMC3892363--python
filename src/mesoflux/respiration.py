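"""Temperature response and partitioning of opaque-chamber respiration fluxes.

Ecosystem respiration is modelled exponentially, R = a e^(bT), fitted by
least squares in log space (ln R = ln a + b T), with the temperature
sensitivity reported as Q10 = exp(10 b) and its standard error by first-order
(delta-method) propagation. Fits are made per developmental stage; a
day/night indicator added to the log-linear model estimates the daytime
suppression of dark respiration; pairing transparent and opaque closures
partitions GPP = Reco - NEE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import StageWindows

MIN_FIT_POINTS = 10


@dataclass
class Q10Fit:
    """Exponential temperature-response fit for one stage."""

    stage: str
    temperature_variable: str
    a: float  # pre-exponential, umol m-2 s-1
    b: float  # exponent, per deg C
    q10: float  # exp(10 b)
    se_b: float
    se_q10: float  # delta method: q10 * 10 * se_b
    r2: float  # in log space
    n: int
    t_range: tuple[float, float]
    n_excluded_nonpositive: int = 0

    def predict(self, temperature_c: np.ndarray | float) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(temperature_c, dtype=float))


def segment_stages(records: pd.DataFrame, windows: StageWindows) -> pd.DataFrame:
    """Label each record with its developmental stage (S1..S4).

    A boundary day belongs to the stage that starts on it. Timestamps outside
    all windows raise ValueError.
    """
    out = records.copy()
    dates = pd.to_datetime(out["timestamp"]).dt.date
    out["stage"] = [windows.label(d) for d in dates]
    return out


def select_temperature_driver(resp: pd.DataFrame, env: pd.DataFrame,
                              candidates: tuple[str, ...] = (
                                  "t_air_c", "t_surf_c", "t_soil2_c", "t_soil5_c"),
                              per_collar_centering: bool = True,
                              ) -> tuple[str, pd.Series]:
    """Pick the temperature variable that best explains ln(Reco).

    Computes the Pearson correlation between ln(respiration) and each
    candidate variable — taken from the records themselves (e.g. chamber air
    temperature) when present, otherwise joined from the environment log on
    the hour — and returns ``(best, table)``. With multiple collars the
    log-respiration is centred per collar first (a collar fixed effect), so
    replicate level differences do not drown the temperature signal. Ties are
    broken by candidate order (air first, shallower before deeper), so pass
    candidates accordingly.
    """
    flux = resp["flux"] if "flux" in resp.columns else resp["reco"]
    flux = flux.to_numpy(dtype=float)
    mask = np.isfinite(flux) & (flux > 0)
    if mask.sum() < 20:
        raise ValueError("need >= 20 positive respiration fluxes per candidate")
    hours = pd.to_datetime(resp["timestamp"]).dt.floor("h")
    env_idx = env.set_index(pd.to_datetime(env["timestamp"]))
    lnr = np.log(flux[mask])
    if per_collar_centering and "collar_id" in resp.columns:
        collars = resp["collar_id"].to_numpy()[mask]
        lnr = pd.Series(lnr).groupby(collars).transform(
            lambda s: s - s.mean()).to_numpy()
    corr = {}
    for cand in candidates:
        if cand in resp.columns:
            temp = resp[cand].to_numpy(dtype=float)[mask]
        elif cand in env_idx.columns:
            temp = hours.map(env_idx[cand]).to_numpy(dtype=float)[mask]
        else:
            continue
        ok = np.isfinite(temp)
        if ok.sum() < 20:
            continue
        x, y = temp[ok], lnr[ok]
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        corr[cand] = float((xc @ yc) / denom) if denom > 0 else np.nan
    if not corr:
        raise ValueError("no usable temperature candidate")
    table = pd.Series(corr)
    best_val = table.max()
    best = next(c for c in candidates if c in corr and corr[c] == best_val)
    return best, table


def fit_q10(resp: pd.DataFrame, temperature: np.ndarray | str | None = None,
            stage: str = "all") -> Q10Fit:
    """Log-space exponential fit of respiration against temperature.

    ``resp`` must hold positive opaque fluxes in ``flux`` (or ``reco``);
    ``temperature`` is either an array aligned with ``resp`` or the name of a
    column (default ``temperature_c``). Non-positive fluxes are excluded and
    counted; fewer than 10 usable points refuses to fit.
    """
    flux = (resp["flux"] if "flux" in resp.columns else resp["reco"]).to_numpy(float)
    if temperature is None:
        temperature = "temperature_c"
    if isinstance(temperature, str):
        temp = resp[temperature].to_numpy(dtype=float)
    else:
        temp = np.asarray(temperature, dtype=float)
    ok = np.isfinite(flux) & np.isfinite(temp)
    positive = ok & (flux > 0)
    n_excl = int(ok.sum() - positive.sum())
    if positive.sum() < MIN_FIT_POINTS:
        raise ValueError(
            f"refusing Q10 fit on {int(positive.sum())} positive fluxes")
    x, y = temp[positive], np.log(flux[positive])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ln_a, b = res.params
    se_b = float(res.bse[1])
    q10 = float(np.exp(10.0 * b))
    return Q10Fit(stage=stage, temperature_variable=(
        temperature if isinstance(temperature, str) else "array"),
        a=float(np.exp(ln_a)), b=float(b), q10=q10, se_b=se_b,
        se_q10=q10 * 10.0 * se_b, r2=float(res.rsquared),
        n=int(positive.sum()), t_range=(float(x.min()), float(x.max())),
        n_excluded_nonpositive=n_excl)


def fit_q10_by_stage(resp: pd.DataFrame, windows: StageWindows,
                     temperature: str = "temperature_c") -> list[Q10Fit]:
    """One exponential fit per stage window (stages lacking enough positive
    fluxes are skipped)."""
    labelled = segment_stages(resp, windows)
    fits = []
    for stage in StageWindows.LABELS:
        sub = labelled[labelled["stage"] == stage]
        try:
            fits.append(fit_q10(sub, temperature, stage=stage))
        except ValueError:
            continue
    return fits


def q10_fits_frame(fits: list[Q10Fit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "stage": f.stage, "temperature_variable": f.temperature_variable,
        "a": f.a, "b": f.b, "q10": f.q10, "se_b": f.se_b, "se_q10": f.se_q10,
        "r2": f.r2, "n": f.n, "t_min": f.t_range[0], "t_max": f.t_range[1],
        "n_excluded_nonpositive": f.n_excluded_nonpositive,
    } for f in fits])


@dataclass
class SuppressionEstimate:
    """Day:night dark-respiration ratio at equal temperature."""

    ratio: float  # exp(day coefficient); < 1 indicates daytime suppression
    se_ratio: float
    day_coeff: float
    se_day_coeff: float
    b: float
    n_day: int
    n_night: int


def day_night_suppression(resp: pd.DataFrame,
                          day: np.ndarray | None = None,
                          temperature: str = "temperature_c") -> SuppressionEstimate:
    """Estimate daytime suppression of dark respiration.

    Fits ln R = ln a + b T + gamma * 1[day] on positive opaque fluxes and
    returns exp(gamma), the day:night respiration ratio at equal temperature
    (delta-method SE). ``day`` defaults to ``par_out > 0`` on the records.
    """
    flux = (resp["flux"] if "flux" in resp.columns else resp["reco"]).to_numpy(float)
    temp = resp[temperature].to_numpy(dtype=float)
    if day is None:
        day = resp["par_out"].to_numpy(dtype=float) > 0
    day = np.asarray(day, dtype=bool)
    ok = np.isfinite(flux) & np.isfinite(temp) & (flux > 0)
    n_day = int((day & ok).sum())
    n_night = int((~day & ok).sum())
    if n_day == 0 or n_night == 0:
        raise ValueError("need both day and night positive fluxes")
    x = np.column_stack([temp[ok], day[ok].astype(float)])
    res = sm.OLS(np.log(flux[ok]), sm.add_constant(x)).fit()
    gamma = float(res.params[2])
    se_gamma = float(res.bse[2])
    ratio = float(np.exp(gamma))
    return SuppressionEstimate(ratio=ratio, se_ratio=ratio * se_gamma,
                               day_coeff=gamma, se_day_coeff=se_gamma,
                               b=float(res.params[1]),
                               n_day=n_day, n_night=n_night)


def partition_gpp(pairs: pd.DataFrame,
                  night_par_threshold: float = 5.0) -> pd.DataFrame:
    """GPP (positive uptake) from paired same-hour (NEE, Reco) records.

    Under the micrometeorological sign convention GPP = Reco - NEE; negative
    values are clipped to zero and counted in the ``clipped`` column.
    Unpaired rows (either flux missing) raise ValueError.
    """
    if pairs["nee"].isna().any() or pairs["reco"].isna().any():
        missing = pairs[pairs["nee"].isna() | pairs["reco"].isna()]
        raise ValueError(
            f"partition_gpp requires fully paired input; {len(missing)} "
            f"rows missing one flux")
    out = pairs.copy()
    raw = out["reco"] - out["nee"]
    out["gpp"] = raw.clip(lower=0.0)
    out["clipped"] = raw < 0.0
    return out
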