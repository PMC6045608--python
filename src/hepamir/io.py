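"""TSV / YAML readers and writers.

Cohort tables and Ct matrices travel together in one UTF-8 TSV: one row per
subject, clinical/histology columns by name, Ct columns prefixed ``ct_``,
missing values as empty fields, dot-decimal throughout. Every writer output
is re-parseable by the matching reader (round-trip property, tested).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from hepamir.cohort import CohortSpec, REFERENCE_ASSAYS
from hepamir.qpcr import CtMatrix, RelativeLevels

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_levels",
    "read_levels",
    "write_spec_yaml",
    "read_spec_yaml",
]

CT_PREFIX = "ct_"

#: columns the cohort reader recognizes beyond the Ct block
KNOWN_COHORT_COLUMNS = {
    "group", "sex", "dili", "age", "bmi", "waist", "glucose", "triglycerides",
    "cholesterol", "hdl", "ldl", "bilirubin", "albumin", "platelets", "alt",
    "ast", "ggt", "alp", "prothrombin", "hb", "transferrin_sat", "ferritin",
    "hba1c", "insulin", "diabetes_or_ifg", "steatosis_grade", "ballooning",
    "lobular_inflammation", "fibrosis_stage",
}

MANDATORY_COLUMNS = ("group",)


def write_cohort(cohort: pd.DataFrame, ct: CtMatrix, path) -> None:
    """Write cohort table and Ct matrix as a single subject-per-row TSV."""
    merged = cohort.copy()
    for assay in ct.ct.columns:
        merged[CT_PREFIX + assay] = ct.ct[assay]
    merged.to_csv(path, sep="\t", index_label="subject_id", na_rep="")


def read_cohort(path, references: Optional[Sequence[str]] = None
                ) -> tuple[pd.DataFrame, CtMatrix]:
    """Read a cohort TSV back into (cohort table, Ct matrix).

    Non-numeric Ct cells raise with the offending row and column named;
    unknown non-Ct columns are kept with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col="subject_id", dtype=str)
    ct_cols = [c for c in df.columns if c.startswith(CT_PREFIX)]
    cohort_cols = [c for c in df.columns if not c.startswith(CT_PREFIX)]

    missing = [c for c in MANDATORY_COLUMNS if c not in cohort_cols]
    if missing:
        raise ValueError(f"mandatory column(s) missing: {missing}")
    unknown = [c for c in cohort_cols if c not in KNOWN_COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"unknown column(s) kept as-is: {unknown}", stacklevel=2)

    ct_data = {}
    for col in ct_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & (df[col].str.strip() != "") & parsed.isna()]
        if len(bad):
            raise ValueError(f"non-numeric Ct value in column {col!r}, "
                             f"row {bad[0]!r}: {df.loc[bad[0], col]!r}")
        ct_data[col[len(CT_PREFIX):]] = parsed

    cohort = df[cohort_cols].copy()
    for col in cohort_cols:
        if col in ("group", "sex"):
            continue
        if col in ("dili", "diabetes_or_ifg"):
            cohort[col] = cohort[col].map({"True": True, "False": False})
            continue
        cohort[col] = pd.to_numeric(cohort[col], errors="coerce")

    ct_df = pd.DataFrame(ct_data, index=df.index)
    if references is None:
        references = [a for a in REFERENCE_ASSAYS if a in ct_df.columns]
    return cohort, CtMatrix(ct_df, references=list(references))


def write_levels(levels: RelativeLevels, path) -> None:
    levels.levels.to_csv(path, sep="\t", index_label="subject_id", na_rep="")


def read_levels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_spec_yaml(spec: CohortSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def read_spec_yaml(path) -> CohortSpec:
    return CohortSpec.from_dict(yaml.safe_load(Path(path).read_text()))
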