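"""Participant-table schema: column definitions, CSV I/O and validation.

The pipeline's single interchange format is an RFC-4180 CSV (UTF-8, ``""``
for missing values) with one row per participant. Columns cover
demographics, biomarker status (CSF α-synuclein SAA, DaTscan specific
binding ratios), olfactory and RBD indicators, clinical items used by the
NSD-ISS staging rules, and the six raw cognitive scores of the original
PPMI neuropsychological battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six cognitive scores (five tests; HVLT-R contributes two scores).
COGNITIVE_TESTS: tuple[str, ...] = (
    "hvlt_immediate",
    "hvlt_delayed",
    "jlo",
    "sdmt",
    "lns",
    "fluency",
)

#: column -> (pandas dtype, lower bound, upper bound, may be missing)
_BOUND = {
    "age": ("Float64", 0.0, 120.0, False),
    "education_years": ("Float64", 0.0, 30.0, True),
    "lowest_putamen_sbr": ("Float64", 1e-9, None, True),
    "expected_sbr": ("Float64", 1e-9, None, True),
    "upsit_percentile": ("Float64", 0.0, 100.0, True),
    "rbdsq_total": ("Int64", 0, 13, True),
    "moca_baseline": ("Int64", 0, 30, True),
    "moca_year1": ("Int64", 0, 30, True),
    "updrs_1_1": ("Int64", 0, 4, True),
    "updrs_apathy": ("Int64", 0, 4, True),
    "gds15": ("Int64", 0, 15, True),
}

_BOOLEANS = (
    "saa_positive",
    "psg_confirmed_rbd",
    "self_reported_rbd_dx",
    "dream_enactment",
    "pd_med_use",
    "clonazepam_use",
    "subthreshold_parkinsonism",
    "functional_impairment_any_track",
)

_STRINGS = ("participant_id", "sex", "group_label")

#: canonical column order of the participant CSV
COLUMNS: tuple[str, ...] = (
    _STRINGS
    + ("age", "education_years")
    + _BOOLEANS[:1]
    + ("lowest_putamen_sbr", "expected_sbr", "upsit_percentile", "rbdsq_total")
    + _BOOLEANS[1:]
    + (
        "moca_baseline",
        "moca_year1",
        "updrs_1_1",
        "updrs_apathy",
        "gds15",
    )
    + COGNITIVE_TESTS
)

SEX_LEVELS = ("male", "female")


class SchemaError(ValueError):
    """Raised when a participant table cannot be used by the pipeline."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_schema` — errors block, warnings do not."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise SchemaError("; ".join(self.errors))


def _dtype_map() -> dict[str, str]:
    dtypes: dict[str, str] = {c: "string" for c in _STRINGS}
    for col, (dtype, *_rest) in _BOUND.items():
        dtypes[col] = dtype
    for col in _BOOLEANS:
        dtypes[col] = "boolean"
    for col in COGNITIVE_TESTS:
        dtypes[col] = "Float64"
    return dtypes


def coerce_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with canonical nullable dtypes and column order."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    out = df.copy()
    bool_map = {True: True, False: False, "True": True, "False": False}
    for col, dtype in _dtype_map().items():
        if dtype == "boolean" and out[col].dtype not in ("bool", "boolean"):
            out[col] = out[col].map(lambda v: bool_map.get(v, v))
        out[col] = out[col].astype(dtype)
    return out[list(COLUMNS) + [c for c in out.columns if c not in COLUMNS]]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a participant table as CSV with ``""`` for missing values."""
    df.to_csv(path, index=False, na_rep="")


# columns appended by the staging / norming steps, so that staged and
# scored CSVs round-trip with correct dtypes
_DERIVED_BOOLEANS = (
    "nsd", "dat_deficit", "dat_unevaluable",
    "meets_stage2_motor", "meets_stage2_nonmotor",
    "irbd_confirmed", "rbd_evidence_any", "css_evaluable",
)
_DERIVED_NULLABLE_BOOLEANS = ("hyposmia", "meets_stage2_cognitive")
_DERIVED_STRINGS = ("stage", "cohort_role", "subgroup", "exclusion_reason")


def _coerce_derived(df: pd.DataFrame) -> pd.DataFrame:
    bool_map = {True: True, False: False, "True": True, "False": False}
    for col in _DERIVED_BOOLEANS + _DERIVED_NULLABLE_BOOLEANS:
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].map(bool_map).astype("boolean")
    for col in _DERIVED_STRINGS:
        if col in df.columns:
            df[col] = df[col].astype("string")
    for col in df.columns:
        if col == "css" or col.startswith("z_"):
            df[col] = df[col].astype("Float64").astype(float)
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read a participant CSV (raw, staged or scored), coercing dtypes."""
    raw = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    return _coerce_derived(coerce_cohort(raw))


def validate_schema(df: pd.DataFrame) -> ValidationReport:
    """Check column presence, types and instrument ranges.

    Range violations (e.g. MoCA outside 0–30, RBDSQ outside 0–13,
    percentile outside 0–100) are errors; missing values in columns the
    pipeline can handle (education, year-1 MoCA, individual test scores)
    are warnings because affected participants are simply flagged
    not-evaluable downstream.
    """
    report = ValidationReport()
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        report.errors.append(f"missing required columns: {', '.join(missing)}")
        return report
    try:
        df = coerce_cohort(df)
    except (ValueError, TypeError) as exc:  # un-coercible cell values
        report.errors.append(f"type coercion failed: {exc}")
        return report

    if df["participant_id"].isna().any():
        report.errors.append("participant_id contains missing values")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"]
        report.errors.append(f"duplicate participant_id values: {list(dupes)[:5]}")
    bad_sex = df["sex"].dropna()[~df["sex"].dropna().isin(SEX_LEVELS)]
    if len(bad_sex):
        report.errors.append(f"sex outside {SEX_LEVELS}: {sorted(set(bad_sex))}")

    for col, (_dtype, lo, hi, may_miss) in _BOUND.items():
        vals = df[col]
        if not may_miss and vals.isna().any():
            report.errors.append(f"{col} has missing values but is required")
        present = vals.dropna().astype(float)
        if lo is not None and (present < lo).any():
            report.errors.append(f"{col} below {lo}: {int((present < lo).sum())} rows")
        if hi is not None and (present > hi).any():
            report.errors.append(f"{col} above {hi}: {int((present > hi).sum())} rows")

    n_edu_missing = int(df["education_years"].isna().sum())
    if n_edu_missing:
        report.warnings.append(
            f"{n_edu_missing} participants missing education; "
            "their cognitive summary score will not be evaluable"
        )
    n_moca1 = int(df["moca_year1"].isna().sum())
    if n_moca1:
        report.warnings.append(
            f"{n_moca1} participants missing year-1 MoCA; "
            "they cannot enter the robust reference group"
        )
    n_tests = int(df[list(COGNITIVE_TESTS)].isna().any(axis=1).sum())
    if n_tests:
        report.warnings.append(
            f"{n_tests} participants missing at least one cognitive score"
        )
    return report


def male_indicator(sex: pd.Series) -> pd.Series:
    """0/1 indicator for male sex (the coding used by the norm models)."""
    out = pd.Series(np.where(sex == "male", 1.0, 0.0), index=sex.index)
    out[sex.isna()] = np.nan
    return out
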