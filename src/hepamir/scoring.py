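"""Histological severity scores and serum-based fibrosis/insulin-resistance algorithms.

Histology side: steatosis grading by percentage of steatotic hepatocytes,
NAS (steatosis + lobular inflammation + ballooning, 0-8), SAF activity
(ballooning + lobular inflammation, 0-4) and the advanced-fibrosis class
(F3-F4). Serum side: the standard published FIB-4, APRI, BARD, NFS and
HOMA-IR formulas with the category boundaries used in NAFLD cohort tables
(FIB-4 at 1.30, APRI at 1, BARD at >= 2, NFS at -1.455 / -0.675 / 0.676).

Units: age in years, AST/ALT in IU/L, platelets in 10^3/uL (== 10^9/L),
albumin in g/dL, BMI in kg/m^2, glucose in mg/dL, insulin in uU/mL.

Boundary ties follow the printed inequality symbols of the source tables:
a score exactly at a "<c / >c" cut-off goes to the lower bin (FIB-4, APRI,
NFS); BARD uses ">= 2". ``strict=False`` flips the tie to the upper bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeverityLabels",
    "grade_steatosis",
    "compute_severity",
    "fib4",
    "apri",
    "bard",
    "nfs",
    "homa_ir",
    "score_table",
]

NAS_CLASSES = ("NAS_0-2", "NAS_3-4", "NAS_5-8")
NFS_BINS = ("<-1.455", "-1.455/-0.675", "-0.675/0.676", ">0.676")


@dataclass(frozen=True)
class SeverityLabels:
    nas: int
    nas_class: str
    saf_activity: int
    saf_at_risk: bool       # SAF activity >= 2
    advanced_fibrosis: bool  # fibrosis stage F3 or F4


def grade_steatosis(pct_steatotic_hepatocytes: float) -> int:
    """Grade steatosis from the percentage of steatotic hepatocytes.

    Grade 0: <5%; grade 1: 5-33%; grade 2: >33-66%; grade 3: >66%.
    """
    pct = float(pct_steatotic_hepatocytes)
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"percentage out of [0, 100]: {pct}")
    if pct < 5.0:
        return 0
    if pct <= 33.0:
        return 1
    if pct <= 66.0:
        return 2
    return 3


def _check_ordinal(value, name: str, lo: int, hi: int) -> int:
    v = int(value)
    if v != value or not (lo <= v <= hi):
        raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {value}")
    return v


def compute_severity(steatosis_grade: int, ballooning: int, lobular_inflammation: int,
                     fibrosis_stage: int) -> SeverityLabels:
    """Derive NAS, SAF activity and the at-risk / advanced-fibrosis classes.

    Lobular inflammation is stored 0-2; a grade of 3 (the wider NAS
    convention) is accepted with a warning so NAS totals remain computable.
    """
    st = _check_ordinal(steatosis_grade, "steatosis_grade", 0, 3)
    ball = _check_ordinal(ballooning, "ballooning", 0, 2)
    if lobular_inflammation == 3:
        warnings.warn("lobular inflammation grade 3 accepted for NAS; stored scale is 0-2",
                      stacklevel=2)
        infl = 3
    else:
        infl = _check_ordinal(lobular_inflammation, "lobular_inflammation", 0, 2)
    fib = _check_ordinal(fibrosis_stage, "fibrosis_stage", 0, 4)

    nas = st + infl + ball
    nas_class = NAS_CLASSES[0] if nas <= 2 else (NAS_CLASSES[1] if nas <= 4 else NAS_CLASSES[2])
    saf = ball + infl
    return SeverityLabels(
        nas=nas,
        nas_class=nas_class,
        saf_activity=saf,
        saf_at_risk=saf >= 2,
        advanced_fibrosis=fib in (3, 4),
    )


def _cut(score: float, cutoff: float, strict: bool = True) -> str:
    """Two-bin category with the tie going to the lower bin when strict."""
    if score < cutoff or (strict and score == cutoff):
        return f"<{cutoff:g}"
    return f">{cutoff:g}"


def fib4(age: float, ast: float, alt: float, platelets: float,
         strict: bool = True) -> tuple[float, str]:
    """FIB-4 = (age x AST) / (platelets x sqrt(ALT)); category at 1.30."""
    if alt <= 0:
        raise ValueError(f"ALT must be > 0 for FIB-4, got {alt}")
    if platelets <= 0:
        raise ValueError(f"platelets must be > 0 for FIB-4, got {platelets}")
    if age < 0 or ast < 0:
        raise ValueError("age and AST must be >= 0")
    score = (age * ast) / (platelets * np.sqrt(alt))
    return float(score), _cut(score, 1.30, strict)


def apri(ast: float, platelets: float, ast_uln: float = 40.0,
         strict: bool = True) -> tuple[float, str]:
    """APRI = 100 x (AST / AST upper limit of normal) / platelets; category at 1."""
    if platelets <= 0:
        raise ValueError(f"platelets must be > 0 for APRI, got {platelets}")
    if ast < 0 or ast_uln <= 0:
        raise ValueError("AST must be >= 0 and its upper limit of normal > 0")
    score = 100.0 * (ast / ast_uln) / platelets
    return float(score), _cut(score, 1.0, strict)


def bard(bmi: float, ast: float, alt: float, diabetes: bool) -> tuple[int, str]:
    """BARD = 1·[BMI >= 28] + 2·[AST/ALT >= 0.8] + 1·[diabetes]; category at >= 2."""
    if alt <= 0:
        raise ValueError(f"ALT must be > 0 for BARD, got {alt}")
    if bmi < 0 or ast < 0:
        raise ValueError("BMI and AST must be >= 0")
    score = int(bmi >= 28) + 2 * int(ast / alt >= 0.8) + int(bool(diabetes))
    return score, (">=2" if score >= 2 else "<2")


def nfs(age: float, bmi: float, ifg_or_diabetes: bool, ast: float, alt: float,
        platelets: float, albumin: float, strict: bool = True) -> tuple[float, str]:
    """NAFLD fibrosis score with its published coefficients, binned in four classes.

    NFS = -1.675 + 0.037·age + 0.094·BMI + 1.13·[IFG or diabetes]
          + 0.99·(AST/ALT) - 0.013·platelets - 0.66·albumin
    Bins: <-1.455, -1.455..-0.675, -0.675..0.676, >0.676.
    """
    for name, value in (("age", age), ("bmi", bmi), ("ast", ast), ("alt", alt),
                        ("platelets", platelets), ("albumin", albumin)):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"NFS requires field {name!r}")
    if alt <= 0:
        raise ValueError(f"ALT must be > 0 for NFS, got {alt}")
    if platelets <= 0:
        raise ValueError(f"platelets must be > 0 for NFS, got {platelets}")
    score = (-1.675 + 0.037 * age + 0.094 * bmi + 1.13 * int(bool(ifg_or_diabetes))
             + 0.99 * (ast / alt) - 0.013 * platelets - 0.66 * albumin)

    def below(s: float, c: float) -> bool:
        return s < c or (strict and s == c)

    if below(score, -1.455):
        cat = NFS_BINS[0]
    elif below(score, -0.675):
        cat = NFS_BINS[1]
    elif below(score, 0.676):
        cat = NFS_BINS[2]
    else:
        cat = NFS_BINS[3]
    return float(score), cat


def homa_ir(glucose: float, insulin: float) -> float:
    """HOMA-IR = fasting glucose (mg/dL) x fasting insulin (uU/mL) / 405."""
    if glucose < 0 or insulin < 0:
        raise ValueError("glucose and insulin must be >= 0")
    return float(glucose * insulin / 405.0)


def score_table(cohort: pd.DataFrame, ast_uln: float = 40.0) -> pd.DataFrame:
    """Vectorized severity + serum-score table, one row per subject.

    Expects the cohort columns used by each score; a subject missing an input
    gets NaN for that score rather than failing the whole table.
    """
    out = pd.DataFrame(index=cohort.index)

    hist_ok = cohort[["steatosis_grade", "ballooning", "lobular_inflammation",
                      "fibrosis_stage"]].notna().all(axis=1)
    for col in ("nas", "saf_activity"):
        out[col] = np.nan
    out["nas_class"] = pd.NA
    out["saf_at_risk"] = pd.NA
    out["advanced_fibrosis"] = pd.NA
    for sid in cohort.index[hist_ok]:
        r = cohort.loc[sid]
        sev = compute_severity(int(r["steatosis_grade"]), int(r["ballooning"]),
                               int(r["lobular_inflammation"]), int(r["fibrosis_stage"]))
        out.loc[sid, ["nas", "nas_class", "saf_activity", "saf_at_risk",
                      "advanced_fibrosis"]] = (
            sev.nas, sev.nas_class, sev.saf_activity, sev.saf_at_risk, sev.advanced_fibrosis)

    def per_subject(fn, cols, *extra):
        score = pd.Series(np.nan, index=cohort.index, dtype=float)
        cat = pd.Series(pd.NA, index=cohort.index, dtype=object)
        for sid in cohort.index:
            vals = [cohort.loc[sid, c] for c in cols]
            if any(pd.isna(v) for v in vals):
                continue
            try:
                res = fn(*vals, *extra)
            except ValueError:
                continue
            if isinstance(res, tuple):
                score[sid], cat[sid] = res
            else:
                score[sid] = res
        return score, cat

    out["fib4"], out["fib4_cat"] = per_subject(fib4, ["age", "ast", "alt", "platelets"])
    out["apri"], out["apri_cat"] = per_subject(apri, ["ast", "platelets"], ast_uln)
    out["bard"], out["bard_cat"] = per_subject(bard, ["bmi", "ast", "alt", "diabetes_or_ifg"])
    out["nfs"], out["nfs_cat"] = per_subject(
        nfs, ["age", "bmi", "diabetes_or_ifg", "ast", "alt", "platelets", "albumin"])
    out["homa"], _ = per_subject(homa_ir, ["glucose", "insulin"])
    return out
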