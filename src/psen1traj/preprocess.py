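"""Build the model-ready analysis table from raw visit-level data.

Responsibilities: compute EYO (visit age minus expected age at onset), average
bilateral volumes and adjust them for total intracranial volume (residual
method), form the 7-region bilateral cortical composite PiB SUVR, code
categorical covariates against their reference levels (sex F, APOE e4
non-carrier, group NC), and flag complete cases per outcome. Image processing
is upstream; this module starts from tabular regional values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .synthetic_cohort import PIB_REGIONS

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "MODEL_OUTCOMES",
    "IcvReference",
    "read_cohort",
    "compute_eyo",
    "fit_icv_reference",
    "adjust_icv",
    "composite_suvr",
    "assemble",
    "write_table",
]

REQUIRED_COLUMNS = (
    "subject_id", "family_id", "group", "visit", "visit_age", "sex", "apoe4",
    "education", "expected_aao",
)

#: Analysis outcome names in the assembled table.
MODEL_OUTCOMES = ("mmse", "cdr_sb", "hv", "pib", "ptau181", "ab4240")

_SUVR_COLS = tuple(
    f"pib_suvr_{r}_{h}" for r in PIB_REGIONS for h in ("lh", "rh")
)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a delimited cohort file ('NA' = missing) with schema validation.

    Errors name the offending column and 1-based data line numbers.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for col in ("visit_age", "education", "expected_aao"):
        bad = df.index[~(pd.to_numeric(df[col], errors="coerce").notna()
                         | df[col].isna())]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValidationError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
    bad_group = df.index[~df["group"].isin(["NC", "CY", "TM"])]
    if len(bad_group):
        lines = ", ".join(str(i + 2) for i in bad_group[:5])
        raise ValidationError(
            f"{path}: unknown group labels at line(s) {lines}"
        )
    return df


def compute_eyo(visit_age, expected_aao):
    """EYO = visit age - expected age at onset; negative is pre-symptomatic.

    Missing AAO yields missing EYO (the row is retained; EYO models drop it).
    """
    age = np.asarray(visit_age, dtype=float)
    aao = np.asarray(expected_aao, dtype=float)
    if np.any(aao[np.isfinite(aao)] <= 0):
        raise InputError("expected_aao must be positive")
    return age - aao


@dataclass(frozen=True)
class IcvReference:
    """Fitted ICV adjustment: slope of volume on ICV plus the sample means."""

    slope: float
    mean_icv: float
    mean_volume: float


def fit_icv_reference(volume, icv) -> IcvReference:
    """Least-squares slope of volume on ICV over the (complete-case) sample."""
    v = np.asarray(volume, dtype=float)
    c = np.asarray(icv, dtype=float)
    ok = np.isfinite(v) & np.isfinite(c)
    if ok.sum() < 3:
        raise InputError("need at least 3 complete (volume, icv) pairs")
    if np.any(c[ok] <= 0):
        raise InputError("icv must be positive")
    vm, cm = v[ok].mean(), c[ok].mean()
    denom = np.sum((c[ok] - cm) ** 2)
    slope = 0.0 if denom == 0 else float(np.sum((c[ok] - cm) * (v[ok] - vm)) / denom)
    return IcvReference(slope=slope, mean_icv=float(cm), mean_volume=float(vm))


def adjust_icv(volume, icv, reference: IcvReference):
    """Residual-method head-size correction, preserving the sample mean:
    adjusted = volume - slope * (icv - mean_icv)."""
    v = np.asarray(volume, dtype=float)
    c = np.asarray(icv, dtype=float)
    if np.any(c[np.isfinite(c)] <= 0):
        raise InputError("icv must be positive")
    return v - reference.slope * (c - reference.mean_icv)


def composite_suvr(df: pd.DataFrame) -> pd.Series:
    """Unweighted mean over the 14 regional SUVRs (7 regions x 2 hemispheres).

    Rows with any required region missing get a missing composite, logged.
    """
    missing_cols = [c for c in _SUVR_COLS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing SUVR columns: {missing_cols}")
    block = df[list(_SUVR_COLS)]
    incomplete = block.isna().any(axis=1)
    if incomplete.any():
        ids = df.loc[incomplete, "subject_id"].unique() if "subject_id" in df else []
        logger.info(
            "composite SUVR missing for %d row(s) (incomplete regions): %s",
            int(incomplete.sum()), ", ".join(map(str, ids[:10])),
        )
    out = block.mean(axis=1)
    out[incomplete] = np.nan
    return out


def assemble(raw: pd.DataFrame, icv_reference_group: str | None = None) -> pd.DataFrame:
    """Produce the model-ready table. Idempotent: derived columns are always
    recomputed from the raw columns, so assembling twice equals once.

    icv_reference_group: fit the ICV slope on that group only (e.g., 'NC');
    default fits on the full analysis sample.
    """
    df = raw.copy()
    dup = df.duplicated(subset=["subject_id", "visit"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["subject_id", "visit"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise ValidationError(
            "duplicate (subject, visit) keys: "
            + ", ".join(f"({s},{v})" for s, v in keys)
        )

    df["eyo"] = compute_eyo(df["visit_age"], df["expected_aao"])
    n_no_eyo = int(df["eyo"].isna().sum())
    if n_no_eyo:
        logger.info(
            "%d row(s) lack EYO (missing AAO); retained but excluded from "
            "EYO models: %s", n_no_eyo,
            ", ".join(df.loc[df["eyo"].isna(), "subject_id"].unique()[:10]),
        )

    # bilateral hippocampal volume, then ICV residual adjustment
    if {"hv_left", "hv_right"}.issubset(df.columns):
        bilateral = (df["hv_left"] + df["hv_right"]) / 2.0
        if "icv" in df.columns:
            mask = (
                df["group"].eq(icv_reference_group)
                if icv_reference_group is not None
                else pd.Series(True, index=df.index)
            )
            ref = fit_icv_reference(bilateral[mask], df.loc[mask, "icv"])
            df["hv"] = adjust_icv(bilateral, df["icv"], ref)
        else:
            df["hv"] = bilateral

    if all(c in df.columns for c in _SUVR_COLS):
        df["pib"] = composite_suvr(df)

    rename = {"csf_ptau181": "ptau181", "csf_ab42_ab40": "ab4240"}
    for src, dst in rename.items():
        if src in df.columns:
            df[dst] = df[src]

    # categorical coding against reference levels
    df["sex_M"] = (df["sex"] == "M").astype(float)
    df["apoe4_carrier"] = (df["apoe4"] == "carrier").astype(float)
    df["group"] = pd.Categorical(df["group"], categories=["NC", "CY", "TM"])

    # codon-200 alternative grouping for carriers
    if "codon" in df.columns:
        codon = pd.to_numeric(df["codon"], errors="coerce")
        df["codon_group"] = np.where(
            codon.isna(), "NA", np.where(codon < 200, "pre200", "post200")
        )

    covars = ["eyo", "visit_age", "sex_M", "apoe4_carrier", "education"]
    for out in MODEL_OUTCOMES:
        if out in df.columns:
            df[f"cc_{out}"] = (
                df[[out] + covars].notna().all(axis=1).astype(bool)
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="NA", float_format="%.10g")
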