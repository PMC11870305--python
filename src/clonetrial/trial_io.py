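"""Data model and file formats for clonal field-trial measurements.

A trial dataset is a long-format :class:`pandas.DataFrame` with one row per
individual-tree measurement, keyed by ``(site, block, clone, ramet, age,
trait)``.  Traits are tree height (m), diameter at breast height DBH (cm)
and stem volume (m^3).  Volume is a derived trait: it is computed from DBH
and height through an allometric power formula, never measured directly.

Climate tables hold one row per (site, year) of the 17 ClimateAP-style
bioclimatic variables (MAT, MWMT, MCMT, TD, MAP, AHM, degree-days, NFFD,
PAS, EMT, EXT, Eref, CMD, RH).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TRAITS = ("height", "dbh", "volume")

TRIAL_COLUMNS = ["site", "block", "clone", "ramet", "age", "trait", "value"]
KEY_COLUMNS = ["site", "block", "clone", "ramet", "age", "trait"]

#: Sentinel ramet identifier marking plot-mean (ramet-averaged) rows.
PLOT_MEAN_RAMET = "_plot"

#: Canonical climate-variable names; "<"/">" spelled lt/gt for file safety.
CLIMATE_VARIABLES = [
    "MAT", "MWMT", "MCMT", "TD", "MAP", "AHM",
    "DD_lt_0", "DD_gt_5", "DD_lt_18", "DD_gt_18",
    "NFFD", "PAS", "EMT", "EXT", "Eref", "CMD", "RH",
]
CLIMATE_COLUMNS = ["site", "year"] + CLIMATE_VARIABLES

# Allometric stem-volume coefficients for Catalpa bungei: V = a * DBH^b * H^c
# with DBH in cm, height in m, volume in m^3.
_VOL_A = 0.000050479055
_VOL_B = 1.9085054
_VOL_C = 0.99076507


class TrialDataError(ValueError):
    """Raised when a trial or climate table violates the data contract."""


def estimate_volume(dbh, height):
    """Stem volume (m^3) from DBH (cm) and height (m).

    Vectorized allometric formula ``V = a * DBH^b * H^c``; strictly
    increasing in each argument when both are positive, zero when either
    is zero.

    Raises
    ------
    ValueError
        if any input is negative.
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh < 0) or np.any(height < 0):
        raise ValueError("DBH and height must be nonnegative")
    out = _VOL_A * dbh**_VOL_B * height**_VOL_C
    if out.ndim == 0:
        return float(out)
    return out


def validate_trial(df: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; returns the (possibly re-typed) frame.

    Enforces: canonical columns, known trait names, nonnegative finite
    values, positive integer ages, and uniqueness of the six-column key.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    for col in ("site", "block", "clone", "ramet", "trait"):
        df[col] = df[col].astype(str)
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)

    bad_traits = sorted(set(df["trait"]) - set(TRAITS))
    if bad_traits:
        raise TrialDataError(f"unknown trait names: {bad_traits}")
    if (df["age"] <= 0).any():
        row = df.index[df["age"] <= 0][0]
        raise TrialDataError(f"non-positive age at row {row}")
    if (~np.isfinite(df["value"])).any() or (df["value"] < 0).any():
        row = df.index[(~np.isfinite(df["value"])) | (df["value"] < 0)][0]
        raise TrialDataError(f"invalid (negative or non-finite) value at row {row}")

    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        first = df.loc[dup, KEY_COLUMNS].iloc[0].tolist()
        raise TrialDataError(f"duplicate observation key: {tuple(first)}")
    return df


def read_trial_csv(path) -> pd.DataFrame:
    """Read a long-format trial CSV and validate it.

    The file must carry the seven canonical columns
    ``site,block,clone,ramet,age,trait,value`` (UTF-8, '.' decimal).
    Errors identify the offending row.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise TrialDataError(f"{path}: missing columns {missing}")
    for col in ("value", "age"):
        try:
            # .astype(float) is correctly rounded (pd.to_numeric is not)
            raw[col] = raw[col].astype(float)
        except (ValueError, TypeError):
            bad = (
                pd.to_numeric(raw[col], errors="coerce").isna()
                & raw[col].notna()
            )
            row = int(raw.index[bad][0]) + 2  # 1-based, after header
            raise TrialDataError(
                f"{path}: non-numeric {col} at file line {row}"
            ) from None
    return validate_trial(raw)


def write_trial_csv(df: pd.DataFrame, path) -> None:
    """Write a validated trial table; read∘write is the identity."""
    validate_trial(df).to_csv(path, index=False)


def plot_means(df: pd.DataFrame) -> pd.DataFrame:
    """Average measurements over ramets within each plot.

    Returns one row per (site, block, clone, age, trait) holding the
    arithmetic mean over ramets, with the ramet id set to the sentinel
    :data:`PLOT_MEAN_RAMET`.  Under a balanced design with n ramets per
    plot this rescales the residual variance by 1/n while leaving clone
    and clone-by-site components untouched.
    """
    df = validate_trial(df)
    grouped = (
        df.groupby(["site", "block", "clone", "age", "trait"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    grouped["ramet"] = PLOT_MEAN_RAMET
    return grouped[TRIAL_COLUMNS]


def add_volume(df: pd.DataFrame, check_tolerance: float = 0.05) -> pd.DataFrame:
    """Derive volume rows from matching height and DBH rows.

    Any volume rows already present are kept but cross-checked against the
    allometric formula; deviations beyond ``check_tolerance`` (relative)
    trigger a warning.  Trees missing either parent trait contribute no
    volume row.
    """
    df = validate_trial(df)
    wide = df.pivot_table(
        index=["site", "block", "clone", "ramet", "age"],
        columns="trait", values="value", aggfunc="first",
    )
    have = wide.notna()
    if "height" not in wide.columns or "dbh" not in wide.columns:
        raise TrialDataError("height and dbh rows are required to derive volume")
    both = have["height"] & have["dbh"]
    derived = estimate_volume(wide.loc[both, "dbh"], wide.loc[both, "height"])
    derived = pd.Series(derived, index=wide.index[both])

    if "volume" in wide.columns:
        given = wide.loc[both, "volume"].dropna()
        ref = derived.reindex(given.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(given - ref) / np.where(ref > 0, ref, np.nan)
        n_bad = int(np.nansum(rel > check_tolerance))
        if n_bad:
            warnings.warn(
                f"{n_bad} supplied volume values deviate >"
                f"{check_tolerance:.0%} from the allometric formula",
                stacklevel=2,
            )

    vol = derived.reset_index()
    vol.columns = ["site", "block", "clone", "ramet", "age", "value"]
    vol["trait"] = "volume"
    keep = df[df["trait"] != "volume"]
    out = pd.concat([keep, vol[TRIAL_COLUMNS]], ignore_index=True)
    return validate_trial(out)


def validate_climate(df: pd.DataFrame, td_tolerance: float = 0.1) -> pd.DataFrame:
    """Check the climate-table contract.

    TD must equal MWMT − MCMT within ``td_tolerance`` (slack for rounded
    sources); MAP nonnegative; RH within [0, 100]; (site, year) unique.
    """
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing climate columns: {missing}")
    df = df[CLIMATE_COLUMNS].copy()
    df["site"] = df["site"].astype(str)
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    for v in CLIMATE_VARIABLES:
        df[v] = pd.to_numeric(df[v], errors="raise").astype(float)
    if df.duplicated(subset=["site", "year"]).any():
        raise TrialDataError("duplicate (site, year) climate rows")
    gap = np.abs(df["TD"] - (df["MWMT"] - df["MCMT"]))
    if (gap > td_tolerance).any():
        row = df.index[gap > td_tolerance][0]
        raise TrialDataError(f"TD != MWMT - MCMT at row {row}")
    if (df["MAP"] < 0).any():
        raise TrialDataError("negative MAP")
    if ((df["RH"] < 0) | (df["RH"] > 100)).any():
        raise TrialDataError("RH outside [0, 100]")
    return df


def read_climate_csv(path) -> pd.DataFrame:
    return validate_climate(pd.read_csv(path))


def write_climate_csv(df: pd.DataFrame, path) -> None:
    validate_climate(df).to_csv(path, index=False)
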