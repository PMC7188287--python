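"""Cohort and clearance file handling.

The cohort exchange format is a plain CSV with one header row and one
row per subject: required columns ``id, age, sex, pcr_mg_dl`` (sex as
m/f or male/female) and optional ``mgfr, mgfr_method, weight_kg,
height_cm`` (missing optionals are empty cells).  Validation never
crashes on bad rows: offending rows are excluded and accounted for
per rule, mirroring a study flow chart.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .equations import EQUATIONS, Sex

__all__ = [
    "read_cohort",
    "validate_cohort",
    "panel_frame",
    "read_plasma_studies",
    "read_urinary_studies",
]

REQUIRED_COLUMNS = ("id", "age", "sex", "pcr_mg_dl")
OPTIONAL_COLUMNS = ("mgfr", "mgfr_method", "weight_kg", "height_cm")

_SEX_MAP = {"m": "male", "male": "male", "f": "female", "female": "female"}


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV, checking the header only (row validation is separate)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")
    return df


def validate_cohort(
    source: Union[str, Path, pd.DataFrame],
    require_mgfr: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate cohort rows; return (validated frame, exclusion log).

    Rules: missing/non-numeric required fields, age < 18, non-positive
    creatinine, unknown sex, and (when ``require_mgfr``) missing or
    non-positive measured GFR.  The exclusion log has one row per
    excluded subject with its 0-based row number and the first rule it
    violated.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else read_cohort(source)
    df = df.reset_index(drop=True)
    exclusions = []

    age = pd.to_numeric(df.get("age"), errors="coerce")
    pcr = pd.to_numeric(df.get("pcr_mg_dl"), errors="coerce")
    sex = df.get("sex").astype(str).str.strip().str.lower().map(_SEX_MAP)
    if "mgfr" in df.columns:
        mgfr = pd.to_numeric(df["mgfr"], errors="coerce")
    else:
        mgfr = pd.Series(np.nan, index=df.index)

    for i in df.index:
        rule = None
        if pd.isna(age[i]):
            rule = "missing_or_invalid_age"
        elif age[i] < 18:
            rule = "age_below_18"
        elif pd.isna(sex[i]):
            rule = "unknown_sex"
        elif pd.isna(pcr[i]) or pcr[i] <= 0:
            rule = "nonpositive_or_missing_pcr"
        elif require_mgfr and (pd.isna(mgfr[i]) or mgfr[i] <= 0):
            rule = "nonpositive_or_missing_mgfr"
        if rule:
            exclusions.append({"row": int(i), "id": df.at[i, "id"], "rule": rule})

    excluded_rows = {e["row"] for e in exclusions}
    keep = [i for i in df.index if i not in excluded_rows]
    out = pd.DataFrame(
        {
            "id": df.loc[keep, "id"].astype(str).values,
            "age": age[keep].values,
            "sex": sex[keep].values,
            "pcr_mg_dl": pcr[keep].values,
            "mgfr": mgfr[keep].values,
        }
    )
    if "mgfr_method" in df.columns:
        out["mgfr_method"] = df.loc[keep, "mgfr_method"].fillna("unknown").values
    else:
        out["mgfr_method"] = "unknown"
    for col in ("weight_kg", "height_cm"):
        if col in df.columns:
            out[col] = pd.to_numeric(df.loc[keep, col], errors="coerce").values
    return out, pd.DataFrame(exclusions, columns=["row", "id", "rule"])


def panel_frame(df: pd.DataFrame, black_coefficient: bool = False) -> pd.DataFrame:
    """Four eGFR columns (one per equation) for a validated cohort frame."""
    out = pd.DataFrame(index=df.index)
    age = df["age"].to_numpy(dtype=float)
    pcr = df["pcr_mg_dl"].to_numpy(dtype=float)
    sex_col = df["sex"].astype(str).to_numpy()
    for name, fn in EQUATIONS.items():
        vals = np.empty(len(df))
        for sex in (Sex.MALE, Sex.FEMALE):
            mask = sex_col == sex.value
            if mask.any():
                kwargs = {"black_coefficient": black_coefficient} if name in ("ckdepi", "mdrd") else {}
                vals[mask] = fn(age[mask], sex, pcr[mask], **kwargs)
        out[name] = vals
    return out


def read_plasma_studies(path: Union[str, Path]) -> dict:
    """Read long-format plasma-clearance CSV into per-study sample tables.

    Expected columns: ``study_id, dose_mg, time_min, conc`` and
    optionally ``weight_kg, height_cm`` (constant within a study).
    Returns ``{study_id: dict}`` with dose, samples, weight, height.
    """
    df = pd.read_csv(path)
    needed = {"study_id", "dose_mg", "time_min", "conc"}
    if not needed <= set(df.columns):
        raise ValueError(f"plasma clearance file needs columns {sorted(needed)}")
    studies = {}
    for sid, grp in df.groupby("study_id", sort=False):
        grp = grp.sort_values("time_min")
        studies[str(sid)] = {
            "dose": float(grp["dose_mg"].iloc[0]),
            "samples": list(zip(grp["time_min"].astype(float), grp["conc"].astype(float))),
            "weight": float(grp["weight_kg"].iloc[0]) if "weight_kg" in grp else None,
            "height": float(grp["height_cm"].iloc[0]) if "height_cm" in grp else None,
        }
    return studies


def read_urinary_studies(path: Union[str, Path]) -> dict:
    """Read urinary-period CSV (``study_id, u_conc, u_flow_ml_min, p_conc``)."""
    df = pd.read_csv(path)
    needed = {"study_id", "u_conc", "u_flow_ml_min", "p_conc"}
    if not needed <= set(df.columns):
        raise ValueError(f"urinary clearance file needs columns {sorted(needed)}")
    studies = {}
    for sid, grp in df.groupby("study_id", sort=False):
        studies[str(sid)] = [
            (float(r.u_conc), float(r.u_flow_ml_min), float(r.p_conc))
            for r in grp.itertuples()
        ]
    return studies
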