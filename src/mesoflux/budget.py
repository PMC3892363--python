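"""Mesocosm carbon budget: flux integration versus stock inventory.

The budget is closed two ways, both in g C per mesocosm with the
micrometeorological sign (negative = net gain by the mesocosm):

* flux balance — the cumulative sum of hourly NEE fluxes over the whole run,
  converted to mass through 3600 s x 12.011e-6 g umol-1 x collar area;
* stock balance — the inventory combination
  -(dC_soil + C_shoot + C_root + C_DOC - C_seed),
  whose leading minus sign puts it on the same scale as the flux estimate.

The +C_DOC term inside the inventory combination is what makes the stock
side commensurable with the CO2-only flux sum: leached carbon no longer sits
in any measured pool, and adding it back means the inventory estimates the
same quantity the chambers integrate. Under exact conservation
(C_seed - int(NEE) - C_DOC = dC_soil + C_shoot + C_root) the two balances
are then identical; adding C_DOC to the flux side as well would count the
same grams twice and offset the two estimates by exactly C_DOC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CARBON_MOLAR_MASS

#: g C per (umol m-2 s-1 held for one hour over one m2)
UMOL_HOUR_TO_G = 3600.0 * CARBON_MOLAR_MASS * 1e-6

STOCK_POOLS = ("d_c_soil", "c_shoot", "c_root", "c_doc", "c_seed")


@dataclass
class StockInventory:
    """Final carbon pools of one mesocosm (g C)."""

    d_c_soil: float  # final minus initial soil C; may be negative
    c_shoot: float
    c_root: float
    c_doc: float
    c_seed: float

    def __post_init__(self) -> None:
        for name in STOCK_POOLS:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite pool {name}")
        if self.c_seed <= 0:
            raise ValueError("c_seed must be positive")
        for name in ("c_shoot", "c_root", "c_doc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CarbonBudget:
    """Both balances and their components for one mesocosm."""

    collar_id: str
    flux_balance: float  # cumulative NEE carbon, g C
    stock_balance: float  # -(dC_soil + C_shoot + C_root + C_DOC - C_seed)
    cumulative_nee_g: float
    cumulative_nee_umol_h: float  # diagnostic: plain sum of hourly fluxes
    c_doc: float
    coverage: float
    chamber: bool = True
    nutrient: bool = False


class CoverageError(ValueError):
    """Hourly flux coverage below the configured minimum."""


def pool_carbon(dry_weight_g: float, c_fraction: float) -> float:
    """Carbon mass of a pool from dry weight and its C mass fraction."""
    if dry_weight_g < 0 or not (0 <= c_fraction <= 1):
        raise ValueError("need dry_weight >= 0 and c_fraction in [0, 1]")
    return dry_weight_g * c_fraction


def area_density(mass_g: float, area_m2: float) -> float:
    """Areal density (g m-2), e.g. sowing density from seed mass and collar area."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return mass_g / area_m2


def doc_carbon(events: pd.DataFrame | list[tuple[float, float]]) -> float:
    """Total DOC carbon (g) from (volume L, concentration mg L-1) events."""
    if isinstance(events, pd.DataFrame):
        vol = events["volume_l"].to_numpy(dtype=float)
        conc = events["conc_mg_l"].to_numpy(dtype=float)
    else:
        arr = np.asarray(events, dtype=float).reshape(-1, 2)
        vol, conc = arr[:, 0], arr[:, 1]
    if (vol < 0).any() or (conc < 0).any():
        raise ValueError("volumes and concentrations must be non-negative")
    return float((vol * conc).sum() * 1e-3)


def cumulative_flux_carbon(fluxes: np.ndarray | pd.Series, area_m2: float,
                           *, expected_hours: int | None = None,
                           min_coverage: float = 0.95,
                           gap_fill_max_h: int = 3) -> tuple[float, float]:
    """Integrate hourly NEE fluxes to g C over the collar area.

    ``fluxes`` holds one value per hour (umol m-2 s-1); NaNs are gaps. Gaps
    up to ``gap_fill_max_h`` consecutive hours are linearly interpolated;
    longer gaps (or missing hours against ``expected_hours``) count against
    coverage, and coverage below ``min_coverage`` raises
    :class:`CoverageError`. Returns ``(g_C, coverage)``.
    """
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    series = pd.Series(np.asarray(fluxes, dtype=float))
    n_total = expected_hours if expected_hours is not None else len(series)
    if len(series) == 0 or n_total == 0:
        raise CoverageError("no fluxes to integrate")
    filled = series.interpolate(limit=gap_fill_max_h, limit_area="inside")
    missing = int(filled.isna().sum()) + max(n_total - len(series), 0)
    coverage = 1.0 - missing / n_total
    if coverage < min_coverage:
        gaps = filled.index[filled.isna()].tolist()[:10]
        raise CoverageError(
            f"flux coverage {coverage:.3f} below {min_coverage} "
            f"(first unfilled gap positions: {gaps})")
    total_umol_h = float(filled.dropna().sum())
    return total_umol_h * UMOL_HOUR_TO_G * area_m2, coverage


def stock_balance(inv: StockInventory | dict | pd.Series) -> float:
    """Inventory balance -(dC_soil + C_shoot + C_root + C_DOC - C_seed), g C.

    The negative multiplier puts a net C gain (plant growth exceeding seed C)
    on the negative side, directly comparable with the flux estimate.
    """
    if not isinstance(inv, StockInventory):
        inv = StockInventory(**{k: inv[k] for k in STOCK_POOLS})
    return -(inv.d_c_soil + inv.c_shoot + inv.c_root + inv.c_doc - inv.c_seed)


def collar_budget(collar_id: str, hourly_nee: np.ndarray | pd.Series,
                  inventory_row: pd.Series | dict, doc_events: pd.DataFrame,
                  area_m2: float, *, expected_hours: int | None = None,
                  min_coverage: float = 0.95, gap_fill_max_h: int = 3) -> CarbonBudget:
    """Assemble one collar's :class:`CarbonBudget` from its pieces."""
    nee_g, coverage = cumulative_flux_carbon(
        hourly_nee, area_m2, expected_hours=expected_hours,
        min_coverage=min_coverage, gap_fill_max_h=gap_fill_max_h)
    c_doc = doc_carbon(doc_events)
    return CarbonBudget(
        collar_id=collar_id,
        flux_balance=nee_g,
        stock_balance=stock_balance(inventory_row),
        cumulative_nee_g=nee_g,
        cumulative_nee_umol_h=float(pd.Series(
            np.asarray(hourly_nee, dtype=float)).dropna().sum()),
        c_doc=c_doc,
        coverage=coverage,
        chamber=bool(inventory_row.get("chamber", True)),
        nutrient=bool(inventory_row.get("nutrient", False)),
    )


def budgets_frame(budgets: list[CarbonBudget]) -> pd.DataFrame:
    return pd.DataFrame([{
        "collar_id": b.collar_id, "chamber": b.chamber, "nutrient": b.nutrient,
        "flux_balance": b.flux_balance, "stock_balance": b.stock_balance,
        "cumulative_nee_g": b.cumulative_nee_g,
        "cumulative_nee_umol_h": b.cumulative_nee_umol_h,
        "c_doc": b.c_doc, "coverage": b.coverage,
    } for b in budgets])


def compare_balances(budgets: pd.DataFrame,
                     grouping: str | None = "nutrient") -> dict:
    """Compare flux- and stock-based balances across a collar ensemble.

    Returns a report dict with per-collar differences, group means +- SD, the
    paired mean difference and its t statistic, the RMSE about the 1:1 line,
    the OLS slope/intercept of flux on stock, and one-way ANOVA F across
    treatment groups for each balance type. Needs >= 2 complete budgets;
    grouping columns with singleton groups are rejected for the ANOVA.
    """
    df = budgets.dropna(subset=["flux_balance", "stock_balance"])
    if len(df) < 2:
        raise ValueError("need >= 2 budgets with both balances")
    flux = df["flux_balance"].to_numpy(dtype=float)
    stock = df["stock_balance"].to_numpy(dtype=float)
    diff = flux - stock
    t_stat, p_val = stats.ttest_rel(flux, stock)
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    sxx = float(((stock - stock.mean()) ** 2).sum())
    slope = float(((stock - stock.mean()) * (flux - flux.mean())).sum() / sxx) \
        if sxx > 0 else np.nan
    intercept = float(flux.mean() - slope * stock.mean()) if sxx > 0 else np.nan

    report: dict = {
        "n": int(len(df)),
        "per_collar_difference": dict(zip(df["collar_id"], diff)),
        "mean_difference": float(diff.mean()),
        "sd_difference": float(diff.std(ddof=1)),
        "paired_t": float(t_stat), "paired_p": float(p_val),
        "rmse_1to1": rmse,
        "slope": slope, "intercept": intercept,
        "flux_mean": float(flux.mean()), "flux_sd": float(flux.std(ddof=1)),
        "stock_mean": float(stock.mean()), "stock_sd": float(stock.std(ddof=1)),
    }
    if grouping is not None and grouping in df.columns:
        groups = [g for _, g in df.groupby(grouping)]
        if any(len(g) < 2 for g in groups):
            raise ValueError("singleton treatment groups: ANOVA undefined")
        report["group_means"] = {
            str(key): {"flux": float(g["flux_balance"].mean()),
                       "flux_sd": float(g["flux_balance"].std(ddof=1)),
                       "stock": float(g["stock_balance"].mean()),
                       "stock_sd": float(g["stock_balance"].std(ddof=1)),
                       "n": int(len(g))}
            for key, g in df.groupby(grouping)}
        for kind in ("flux_balance", "stock_balance"):
            f, p = stats.f_oneway(*[g[kind].to_numpy(dtype=float)
                                    for g in groups])
            report[f"anova_{kind}"] = {"F": float(f), "p": float(p)}
    return report
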