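"""Per-sample host metadata: reading, validation and typing.

A metadata table has one row per sample (indexed by ``sample_id``) and
describes the host: individual identity, cohort (adult vs juvenile), juvenile
age-class in days post-hatching, nest, colony, breeding year, sampling date
(ordinal day of year), social-parent identities and paternity flags.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "OPTIONAL_COLUMNS", "read_metadata", "write_metadata",
           "validate_metadata", "check_pairing"]

REQUIRED_COLUMNS = ("sample_id", "individual_id", "cohort", "colony_id", "year")
OPTIONAL_COLUMNS = (
    "age_class", "nest_id", "sampling_date", "social_mother_id",
    "social_father_id", "is_extra_pair", "is_parasitic", "sex",
)
COHORTS = ("adult", "juvenile")


def _to_bool(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    out[series.isna()] = pd.NA
    return out.astype("boolean")


def read_metadata(path) -> pd.DataFrame:
    """Read a tab-separated metadata table and return a typed frame.

    Missing optional columns are created as nulls; boolean flags default to
    False where absent. Raises on missing required columns or duplicate
    sample ids; warns on juveniles without an age-class.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"metadata schema error: missing required column(s) {missing}")
    return validate_metadata(raw)


def validate_metadata(raw: pd.DataFrame) -> pd.DataFrame:
    """Type, index and sanity-check a raw metadata frame."""
    frame = raw.copy()
    if "sample_id" in frame.columns:
        frame = frame.set_index("sample_id")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id: {dup}")
    for col in OPTIONAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA

    frame["cohort"] = frame["cohort"].astype(str).str.strip().str.lower()
    bad = sorted(set(frame["cohort"]) - set(COHORTS))
    if bad:
        raise ValueError(f"unknown cohort value(s): {bad}; expected {COHORTS}")
    frame["year"] = pd.to_numeric(frame["year"]).astype(int)
    frame["age_class"] = pd.to_numeric(frame["age_class"], errors="coerce").astype("Int64")
    frame["sampling_date"] = pd.to_numeric(
        frame["sampling_date"], errors="coerce"
    ).astype("Int64")
    for col in ("is_extra_pair", "is_parasitic"):
        if frame[col].dtype != "boolean":
            frame[col] = _to_bool(frame[col])
        frame[col] = frame[col].fillna(False)

    juv = frame["cohort"] == "juvenile"
    if (juv & frame["age_class"].isna()).any():
        n = int((juv & frame["age_class"].isna()).sum())
        warnings.warn(f"{n} juvenile sample(s) without an age_class", UserWarning)
    adult_aged = ~juv & frame["age_class"].notna()
    if adult_aged.any():
        warnings.warn(
            f"age_class set for {int(adult_aged.sum())} adult sample(s); clearing",
            UserWarning,
        )
        frame.loc[adult_aged, "age_class"] = pd.NA
    return frame


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_pairing(table, metadata: pd.DataFrame) -> None:
    """Require exactly one metadata row for every sample of a table."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:10]}")
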