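"""Covariate derivation, BQL handling and feature-matrix assembly.

Derives body surface area and Schwartz eGFR from the raw demographics and
labs, applies the below-quantitation substitution rule (half the 0.25 mg/L
LLOQ), classifies troughs against the 1.0-5.5 mg/L therapeutic window,
imputes missing covariates with training-set medians, and assembles the
candidate feature matrix for the selection/ML stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structural import LLOQ, DataError

__all__ = [
    "compute_bsa",
    "egfr_schwartz",
    "apply_bql",
    "apply_bql_frame",
    "in_therapeutic_window",
    "impute_missing",
    "derive_covariates",
    "build_feature_matrix",
    "LAB_COLUMNS",
    "COMED_COLUMNS",
    "DEFAULT_CANDIDATES",
]

#: laboratory covariates, Table-1 units
LAB_COLUMNS = [
    "WBC", "NPCT", "LPCT", "RBC", "HGB", "ALB", "PLT", "CRP",
    "TBIL", "DBIL", "ALT", "AST", "ALP", "SCR", "INR", "DDR",
]

#: co-medication indicator columns
COMED_COLUMNS = ["TAC", "SIRO", "CSA", "PPI", "GCS"]

#: candidate features offered to Boruta.  Raw height is deliberately left
#: out (it enters through BSA); the list is configurable at the call site.
DEFAULT_CANDIDATES = (
    ["AGE", "SEX", "WT", "BSA", "EGFR", "TDOSE"]
    + LAB_COLUMNS
    + COMED_COLUMNS
    + ["CL", "V"]
)

#: therapeutic trough window, mg/L (both ends inclusive)
WINDOW_LO, WINDOW_HI = 1.0, 5.5


def compute_bsa(height, weight):
    """Body surface area (m^2) = sqrt(height_cm * weight_kg / 3600)."""
    height = np.asarray(height, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any(height <= 0) or np.any(weight <= 0):
        raise DataError("height and weight must be > 0")
    out = np.sqrt(height * weight / 3600.0)
    return out if out.ndim else float(out)


def egfr_schwartz(height, scr, age_months):
    """Schwartz estimated GFR (mL/min/1.73 m^2).

    k * height_cm / (SCR_umol_per_L / 88.4), with k = 0.45 below 12 months
    and k = 0.413 from 12 to 24 months.  SCR is reported in umol/L and
    converted to mg/dL by the standard factor 88.4.
    """
    height = np.asarray(height, dtype=float)
    scr = np.asarray(scr, dtype=float)
    age_months = np.asarray(age_months, dtype=float)
    if np.any(scr <= 0):
        raise DataError("serum creatinine must be > 0")
    k = np.where(age_months < 12.0, 0.45, 0.413)
    out = k * height / (scr / 88.4)
    return out if out.ndim else float(out)


def apply_bql(conc, lloq: float = LLOQ):
    """Below-quantitation rule: conc < LLOQ -> (LLOQ/2, flagged True).

    Idempotent: the substituted value LLOQ/2 is itself below LLOQ and maps
    to the same value again.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise DataError("concentration must be >= 0")
    flag = conc < lloq
    out = np.where(flag, lloq / 2.0, conc)
    if out.ndim:
        return out, flag
    return float(out), bool(flag)


def apply_bql_frame(df: pd.DataFrame, lloq: float = LLOQ) -> pd.DataFrame:
    """Apply the BQL rule to the DV column, setting the BQL flag column."""
    out = df.copy()
    dv, flag = apply_bql(out["DV"].to_numpy(), lloq)
    out["DV"] = dv
    out["BQL"] = flag.astype(int)
    return out


def in_therapeutic_window(conc):
    """Classify a trough against the 1.0-5.5 mg/L target window.

    Returns 'sub', 'in' or 'supra'; both boundaries count as inside.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise DataError("concentration must be >= 0")
    out = np.where(conc < WINDOW_LO, "sub", np.where(conc > WINDOW_HI, "supra", "in"))
    return out if out.ndim else str(out)


def impute_missing(matrix: pd.DataFrame, medians: pd.Series | None = None,
                   max_missing_frac: float = 0.30):
    """Median-impute missing cells; returns (imputed frame, medians used).

    When ``medians`` is None they are computed from this (training) frame
    and should be frozen and passed back in for validation/external data so
    no information leaks across the split.  A column missing >= 30% of its
    values violates the inclusion criteria and raises.
    """
    out = matrix.copy()
    num = out.select_dtypes(include=[np.number]).columns
    if medians is None:
        frac = out[num].isna().mean()
        bad = frac[frac >= max_missing_frac]
        if len(bad):
            raise DataError(
                "column(s) with >=30% missing values: " + ", ".join(bad.index)
            )
        medians = out[num].median()
    if medians.isna().any():
        bad = medians[medians.isna()].index
        raise DataError("no training values to impute from: " + ", ".join(bad))
    out[num] = out[num].fillna(medians)
    return out, medians


def derive_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add BSA, EGFR and total daily dose columns to a TDM-event frame."""
    out = df.copy()
    out["BSA"] = compute_bsa(out["HT"].to_numpy(), out["WT"].to_numpy())
    out["EGFR"] = egfr_schwartz(
        out["HT"].to_numpy(), out["SCR"].to_numpy(), out["AGE"].to_numpy()
    )
    out["TDOSE"] = out["AMT"].to_numpy() * (24.0 / out["II"].to_numpy())
    return out


def build_feature_matrix(df: pd.DataFrame, ebes: pd.DataFrame | None = None,
                         candidates: list[str] | None = None) -> pd.DataFrame:
    """Assemble the ML design: candidate columns plus the CONC target.

    ``ebes`` is the per-subject empirical-Bayes table (ID, CL_IND, V_IND)
    from the population fit; its CL/V become the CL and V features.  Noise
    columns present in ``df`` (NOISE*) are appended to the candidate set.
    """
    work = derive_covariates(df) if "BSA" not in df.columns else df.copy()
    if ebes is not None:
        merged = work.merge(
            ebes[["ID", "CL_IND", "V_IND"]].rename(columns={"CL_IND": "CL", "V_IND": "V"}),
            on="ID", how="left",
        )
    else:
        merged = work
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in merged.columns]
        candidates += [c for c in merged.columns if c.startswith("NOISE")]
    missing = [c for c in candidates if c not in merged.columns]
    if missing:
        raise DataError("missing candidate columns: " + ", ".join(missing))
    out = merged[candidates].copy()
    out["CONC"] = merged["DV"].to_numpy()
    return out
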