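"""Transparent-chamber light-attenuation correction for NEE fluxes.

A transparent chamber lid transmits only a fraction tau of ambient PAR, so
daytime NEE measured inside the chamber underestimates net uptake. The
correction (i) estimates tau by a through-origin regression of inside on
outside PAR, (ii) fits a plot-level light response of NEE uptake against PAR
(logarithmic by default: uptake = a ln(PAR) + c, with uptake = -NEE stored
positive), and (iii) adds the offset between the light response evaluated at
ambient and at chamber PAR,

    delta(PAR) = f(PAR / tau) - f(PAR),

to every daytime transparent flux from the net-uptake onset date onward. For
the logarithmic form the offset is a * ln(1/tau), constant in PAR.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .chamber import has_flag
from .config import RunConfig


class ExtrapolationWarning(UserWarning):
    """Correction evaluated outside the fitted PAR domain."""


@dataclass
class AttenuationModel:
    """Lid PAR transmission from paired outside/inside readings."""

    transmission: float  # tau
    r2: float
    n: int

    @property
    def attenuation(self) -> float:
        return 1.0 - self.transmission

    def __post_init__(self) -> None:
        if not (0.0 < self.transmission <= 1.0 + 1e-9):
            raise ValueError("transmission must be in (0, 1]")


@dataclass
class LightResponseModel:
    """Fitted NEE-uptake light response (uptake stored positive)."""

    form: str  # "log" | "hyperbola"
    coeffs: tuple[float, float]  # log: (a, c); hyperbola: (amax, k)
    r2: float
    n: int
    par_domain: tuple[float, float]

    def predict_uptake(self, par: np.ndarray | float) -> np.ndarray:
        par = np.asarray(par, dtype=float)
        if np.any(par <= 0):
            raise ValueError("light response is defined for PAR > 0")
        if self.form == "log":
            a, c = self.coeffs
            return a * np.log(par) + c
        amax, k = self.coeffs
        return amax * par / (k + par)


def fit_attenuation(par_out: np.ndarray, par_in: np.ndarray) -> AttenuationModel:
    """Through-origin least squares of inside on outside PAR: tau = Sxy/Sxx.

    A lid transmits a fraction of incident light, so the physically
    meaningful model has no intercept. Requires >= 10 daytime pairs.
    """
    par_out = np.asarray(par_out, dtype=float)
    par_in = np.asarray(par_in, dtype=float)
    mask = par_out > 0
    if not mask.any():
        raise ValueError("no daylight: all outside PAR is zero")
    x, y = par_out[mask], par_in[mask]
    if x.size < 10:
        raise ValueError(f"need >= 10 daytime PAR pairs, got {x.size}")
    tau = float((x @ y) / (x @ x))
    ss_res = float(((y - tau * x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AttenuationModel(transmission=min(tau, 1.0), r2=max(min(r2, 1.0), 0.0),
                            n=int(x.size))


def fit_light_response(records: pd.DataFrame, form: str = "log",
                       min_points: int = 20) -> LightResponseModel:
    """Fit the uptake light response on daytime unflagged transparent records.

    ``records`` must carry ``flux`` and a PAR column (``par_in`` preferred,
    else ``par_out``); uptake is -flux. Only PAR > 0 rows are used; the log
    form (default) is an OLS fit of uptake on ln(PAR), the hyperbola form is
    a nonlinear rectangular-hyperbola fit.
    """
    par_col = "par_in" if "par_in" in records.columns else "par_out"
    par = records[par_col].to_numpy(dtype=float)
    uptake = -records["flux"].to_numpy(dtype=float)
    mask = (par > 0) & np.isfinite(uptake)
    par, uptake = par[mask], uptake[mask]
    if par.size < min_points:
        raise ValueError(
            f"refusing to fit light response on {par.size} points "
            f"(need >= {min_points})")
    if form == "log":
        x = sm.add_constant(np.log(par))
        res = sm.OLS(uptake, x).fit()
        c, a = res.params  # [const, ln(par)]
        r2 = float(res.rsquared)
        coeffs = (float(a), float(c))
    elif form == "hyperbola":
        def hyp(p, amax, k):
            return amax * p / (k + p)
        p0 = (max(uptake.max(), 1.0), max(np.median(par), 1.0))
        popt, _ = curve_fit(hyp, par, uptake, p0=p0, maxfev=10000)
        pred = hyp(par, *popt)
        ss_res = float(((uptake - pred) ** 2).sum())
        ss_tot = float(((uptake - uptake.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        coeffs = (float(popt[0]), float(popt[1]))
    else:
        raise ValueError(f"unknown light response form {form!r}")
    return LightResponseModel(form=form, coeffs=coeffs, r2=r2, n=int(par.size),
                              par_domain=(float(par.min()), float(par.max())))


def correction_offset(model: LightResponseModel, par_in: np.ndarray | float,
                      tau: float) -> np.ndarray:
    """Uptake offset delta = f(par_in / tau) - f(par_in), umol m-2 s-1.

    The extra uptake the mesocosm would have shown at ambient PAR. For the
    log form this is a * ln(1/tau), independent of PAR. Values outside the
    fitted PAR domain raise an :class:`ExtrapolationWarning` but are still
    computed.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")
    par_in = np.asarray(par_in, dtype=float)
    if np.any(par_in <= 0):
        raise ValueError("par_in must be positive")
    ambient = par_in / tau
    lo, hi = model.par_domain
    if np.any((ambient < lo) | (ambient > hi)):
        warnings.warn("ambient PAR outside fitted light-response domain",
                      ExtrapolationWarning, stacklevel=2)
    return model.predict_uptake(ambient) - model.predict_uptake(par_in)


def apply_correction(records: pd.DataFrame,
                     model: "LightResponseModel | dict[str, LightResponseModel]",
                     tau: float, onset_date: dt.date,
                     config: RunConfig | None = None,
                     fallback: LightResponseModel | None = None) -> pd.DataFrame:
    """Attach corrected fluxes to a flux-record frame.

    Transparent daytime records on/after ``onset_date`` get
    ``flux_corrected = flux - delta(par)`` (more negative = more uptake);
    everything else keeps its original flux. ``model`` is either one
    plot-level light response or a per-collar mapping (``fallback`` covers
    collars absent from the mapping). Adds columns ``flux_corrected``,
    ``correction_offset`` and ``corrected_flag``; eligible records with
    missing/zero PAR are flagged ``no_par`` and left uncorrected.
    """
    config = config or RunConfig()
    out = records.copy()
    ts = pd.to_datetime(out["timestamp"])
    eligible = (
        (out["chamber_type"] == "transparent")
        & (ts.dt.date >= onset_date)
        & (out["par_out"].to_numpy(dtype=float) > config.correction_par_threshold)
        & np.isfinite(out["flux"].to_numpy(dtype=float))
    )
    par = (out["par_in"] if config.use_par_in
           else out["par_out"] * tau).to_numpy(dtype=float)
    usable = eligible & np.isfinite(par) & (par > 0)
    missing = eligible & ~usable

    offsets = np.zeros(len(out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        if isinstance(model, dict):
            for cid in out.loc[usable, "collar_id"].unique():
                m = model.get(cid, fallback)
                if m is None:
                    raise ValueError(
                        f"no light response for collar {cid} and no fallback")
                sel = (out["collar_id"] == cid).to_numpy() & usable.to_numpy()
                offsets[sel] = correction_offset(m, par[sel], tau)
        elif usable.any():
            offsets[usable.to_numpy()] = correction_offset(
                model, par[usable.to_numpy()], tau)
    out["correction_offset"] = offsets
    out["flux_corrected"] = out["flux"] - offsets
    out["corrected_flag"] = usable
    if missing.any():
        flags = out.loc[missing, "qc_flags"].fillna("")
        out.loc[missing, "qc_flags"] = [
            ";".join(sorted(set(f.split(";")) - {""} | {"no_par"})) for f in flags]
    return out


def usable_daytime_transparent(records: pd.DataFrame,
                               onset_date: dt.date | None = None) -> pd.DataFrame:
    """Daytime, rain-free, well-fitted transparent records (the light-response
    fitting set), optionally restricted to on/after an onset date."""
    mask = (
        (records["chamber_type"] == "transparent")
        & ~has_flag(records, "night")
        & ~has_flag(records, "rain")
        & ~has_flag(records, "poor_fit")
        & ~has_flag(records, "fit_failed")
    )
    if onset_date is not None:
        mask &= pd.to_datetime(records["timestamp"]).dt.date >= onset_date
    return records[mask]
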