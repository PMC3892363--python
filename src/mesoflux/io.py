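"""CSV dialects and the run manifest.

All artifacts are plain UTF-8 CSV with ISO-8601 timestamps and '.' decimals;
one documented header per dialect, no sniffing. Reading hard-fails on a
missing required column, preserves unknown extra columns, and reports
malformed numeric cells with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

DIALECTS: dict[str, dict] = {
    "traces": {
        "required": ["closure_id", "collar_id", "chamber_type", "timestamp",
                     "t_s", "co2_ppm", "par_in", "par_out", "t_air_c",
                     "volume_m3", "area_m2", "pressure_pa"],
        "numeric": ["t_s", "co2_ppm", "par_in", "par_out", "t_air_c",
                    "volume_m3", "area_m2", "pressure_pa"],
        "datetime": ["timestamp"],
    },
    "env": {
        "required": ["timestamp", "t_air_c", "t_surf_c", "t_soil2_c",
                     "t_soil5_c", "par", "rain"],
        "numeric": ["t_air_c", "t_surf_c", "t_soil2_c", "t_soil5_c", "par"],
        "datetime": ["timestamp"],
    },
    "doc": {
        "required": ["collar_id", "date", "volume_l", "conc_mg_l"],
        "numeric": ["volume_l", "conc_mg_l"],
        "datetime": [],
    },
    "inventory": {
        "required": ["collar_id", "chamber", "nutrient", "d_c_soil",
                     "c_shoot", "c_root", "c_doc", "c_seed"],
        "numeric": ["d_c_soil", "c_shoot", "c_root", "c_doc", "c_seed"],
        "datetime": [],
    },
    "truth": {
        "required": ["collar_id", "timestamp", "shoot_dw", "root_dw", "rhet",
                     "rauto", "reco", "gpp", "nee", "nee_chamber"],
        "numeric": ["shoot_dw", "root_dw", "rhet", "rauto", "reco", "gpp",
                    "nee", "nee_chamber"],
        "datetime": ["timestamp"],
    },
    "fluxes": {
        "required": ["closure_id", "collar_id", "chamber_type", "timestamp",
                     "flux", "slope", "r2", "slope_se", "deadband_s",
                     "window_s", "par_in", "par_out", "temperature_c",
                     "qc_flags"],
        "numeric": ["flux", "slope", "r2", "slope_se", "deadband_s",
                    "window_s", "par_in", "par_out", "temperature_c"],
        "datetime": ["timestamp"],
    },
    "budgets": {
        "required": ["collar_id", "chamber", "nutrient", "flux_balance",
                     "stock_balance", "cumulative_nee_g",
                     "cumulative_nee_umol_h", "c_doc", "coverage"],
        "numeric": ["flux_balance", "stock_balance", "cumulative_nee_g",
                    "cumulative_nee_umol_h", "c_doc", "coverage"],
        "datetime": [],
    },
}
DIALECTS["fluxes_corrected"] = {
    "required": DIALECTS["fluxes"]["required"]
    + ["flux_corrected", "correction_offset", "corrected_flag"],
    "numeric": DIALECTS["fluxes"]["numeric"]
    + ["flux_corrected", "correction_offset"],
    "datetime": ["timestamp"],
}


class CsvFormatError(ValueError):
    """Header mismatch or malformed cells in a dialect CSV."""


def write_csv(frame: pd.DataFrame, path: str | Path, dialect: str) -> None:
    spec = DIALECTS[dialect]
    missing = [c for c in spec["required"] if c not in frame.columns]
    if missing:
        raise CsvFormatError(f"{dialect}: cannot write, missing columns {missing}")
    out = frame.copy()
    for col in spec["datetime"]:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    # shortest round-trip repr: pandas' default vectorised float writer can
    # be one ulp off, which breaks bit-exact round trips
    out.to_csv(path, index=False, lineterminator="\n",
               float_format=lambda x: repr(float(x)))


def read_csv(path: str | Path, dialect: str) -> pd.DataFrame:
    spec = DIALECTS[dialect]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec["required"] if c not in frame.columns]
    if missing:
        raise CsvFormatError(
            f"{path}: header mismatch for dialect {dialect!r}; "
            f"missing columns {missing}")
    for col in spec["numeric"]:
        raw = frame[col].replace("", "nan")
        try:
            # numpy parses via strtod, preserving round-trip reprs exactly
            # (pandas' fast to_numeric parser can be one ulp off)
            frame[col] = raw.to_numpy(dtype="U32").astype(float)
        except ValueError:
            converted = pd.to_numeric(raw, errors="coerce")
            bad = converted.isna() & (raw != "nan")
            # +2: header line plus 1-based numbering
            lines = (frame.index[bad] + 2).tolist()[:10]
            raise CsvFormatError(
                f"{path}: non-numeric value in column {col!r} "
                f"at line(s) {lines}") from None
    for col in spec["datetime"]:
        try:
            frame[col] = pd.to_datetime(frame[col], format="ISO8601")
        except ValueError as exc:
            raise CsvFormatError(f"{path}: bad timestamp in {col!r}: {exc}") from exc
    for col in frame.columns:
        if col in spec["numeric"] or col in spec["datetime"]:
            continue
        if col in ("chamber", "nutrient", "corrected_flag"):
            frame[col] = frame[col].map(
                {"True": True, "False": False, "true": True, "false": False,
                 "1": True, "0": False}).astype(bool)
        elif col == "rain":
            frame[col] = frame[col].map(
                {"True": True, "False": False, "true": True, "false": False,
                 "1": True, "0": False}).astype(bool)
    return frame


def write_manifest(path: str | Path, *, config_hash: str, seed: int,
                   artifacts: dict[str, int]) -> None:
    """Record the run provenance: config hash, seed, and row counts."""
    payload = {"config_hash": config_hash, "seed": seed,
               "artifact_rows": artifacts}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
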