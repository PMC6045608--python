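"""Ratio biomarkers and single-marker diagnostic evaluation.

Empirical ROC curves are built on observed marker values (no interpolation or
smoothing): thresholds sit at the observed scores and tied scores step
diagonally, so the trapezoidal AUROC equals the Mann-Whitney U statistic
divided by n1*n0 with ties counted one half. The operating point is chosen by
the Youden index J = sensitivity + specificity - 1, with ties broken toward
higher sensitivity and then the lower cut-off.

Confidence intervals: Clopper-Pearson exact for the proportion metrics,
Simel's log method for likelihood ratios, Hanley-McNeil (default) or DeLong
for the AUROC. Degenerate cells yield flagged NaN/inf values, never division
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from hepamir.qpcr import RelativeLevels

__all__ = [
    "RocResult",
    "DiagnosticReport",
    "build_ratio_features",
    "empirical_roc",
    "youden_optimal_cutoff",
    "confusion_metrics",
    "metric_confidence_intervals",
    "predictive_values",
    "evaluate_marker",
]

DEFAULT_NUMERATORS = ("miR-34a", "miR-27b", "miR-22", "miR-122", "miR-192", "miR-21")
DEFAULT_DENOMINATORS = ("miR-30c", "miR-16", "miR-197")


def ratio_name(numerator: str, denominator: str) -> str:
    """Compact ratio label, e.g. ('miR-34a', 'miR-197') -> 'miR-34a/197'."""
    den = denominator[4:] if denominator.startswith("miR-") else denominator
    return f"{numerator}/{den}"


def build_ratio_features(levels: RelativeLevels | pd.DataFrame,
                         numerators: Sequence[str] = DEFAULT_NUMERATORS,
                         denominators: Sequence[str] = DEFAULT_DENOMINATORS) -> pd.DataFrame:
    """Per-subject ratios of induced over repressed miRNA levels.

    One feature per (numerator, denominator) pair; missing if either side is
    missing. Levels must be positive (they are by construction of 2^-ddCt).
    """
    lv = levels.levels if isinstance(levels, RelativeLevels) else levels
    for a in list(numerators) + list(denominators):
        if a not in lv.columns:
            raise ValueError(f"assay {a!r} not present in level matrix")
        if (lv[a].dropna() <= 0).any():
            raise ValueError(f"assay {a!r} has non-positive levels")
    out = {}
    for num in numerators:
        for den in denominators:
            out[ratio_name(num, den)] = lv[num] / lv[den]
    return pd.DataFrame(out, index=lv.index)


@dataclass
class RocResult:
    thresholds: np.ndarray          # observed marker values, ascending
    tpr: np.ndarray                 # ROC path including (0,0) and (1,1)
    fpr: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]
    direction: str                  # higher_is_positive | lower_is_positive
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


@dataclass
class DiagnosticReport:
    """Confusion-metric panel at one operating point."""

    counts: tuple[int, int, int, int]   # tp, fp, fn, tn
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    plr: float
    nlr: float
    cutoff: Optional[float] = None
    direction: Optional[str] = None
    ci: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _auroc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUROC as the concordance probability (ties counted one half)."""
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def _hanley_mcneil_ci(a: float, n1: int, n0: int, level: float) -> tuple[float, float]:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, a - z * se), min(1.0, a + z * se))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, level: float) -> tuple[float, float]:
    """DeLong variance from the placement (structural component) values."""
    a = _auroc_mann_whitney(pos, neg)
    v10 = ((pos[:, None] > neg[None, :]).astype(float)
           + 0.5 * (pos[:, None] == neg[None, :])).mean(axis=1)
    v01 = ((pos[:, None] > neg[None, :]).astype(float)
           + 0.5 * (pos[:, None] == neg[None, :])).mean(axis=0)
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, a - z * se), min(1.0, a + z * se))


def empirical_roc(scores: Sequence[float], labels: Sequence[bool],
                  direction: str = "auto", ci_level: float = 0.95,
                  ci_method: str = "hanley_mcneil") -> RocResult:
    """Empirical ROC curve and trapezoidal AUROC.

    ``direction="auto"`` orients the marker so AUROC >= 0.5 and records the
    resolved orientation. Subjects with missing scores are excluded
    (complete-case, as for any single-marker ROC).
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if not y.any() or y.all():
        raise ValueError("both classes must be non-empty")

    pos, neg = s[y], s[~y]
    a_higher = _auroc_mann_whitney(pos, neg)
    if direction == "auto":
        direction = "higher_is_positive" if a_higher >= 0.5 else "lower_is_positive"
    if direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "higher_is_positive" else -1.0
    oriented = sign * s

    # sweep thresholds from the most extreme oriented score downwards
    order = np.argsort(-oriented, kind="mergesort")
    y_sorted = y[order]
    o_sorted = oriented[order]
    distinct = np.r_[np.nonzero(np.diff(o_sorted))[0], len(o_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / y.sum()]
    fpr = np.r_[0.0, fp / (~y).sum()]
    auroc = float(np.trapezoid(tpr, fpr))

    if ci_method == "hanley_mcneil":
        ci = _hanley_mcneil_ci(auroc, int(y.sum()), int((~y).sum()), ci_level)
    elif ci_method == "delong":
        ci = _delong_ci(sign * pos, sign * neg, ci_level)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return RocResult(
        thresholds=np.unique(s),
        tpr=tpr,
        fpr=fpr,
        auroc=auroc,
        auroc_ci=(float(ci[0]), float(ci[1])),
        direction=direction,
        scores=s,
        labels=y,
    )


@dataclass
class YoudenResult:
    cutoff: float
    j: float
    sensitivity: float
    specificity: float


def youden_optimal_cutoff(roc: RocResult) -> YoudenResult:
    """Cut-off maximizing J = sensitivity + specificity - 1 over observed values.

    A positive call is score >= cutoff (higher_is_positive) or score <= cutoff
    (lower_is_positive). Ties in J resolve toward higher sensitivity, then the
    lower cut-off.
    """
    s, y = roc.scores, roc.labels
    higher = roc.direction == "higher_is_positive"
    best: Optional[YoudenResult] = None
    for t in roc.thresholds:
        call = (s >= t) if higher else (s <= t)
        sens = float((call & y).sum() / y.sum())
        spec = float((~call & ~y).sum() / (~y).sum())
        j = sens + spec - 1.0
        cand = YoudenResult(float(t), j, sens, spec)
        if best is None:
            best = cand
            continue
        key_new = (round(j, 12), round(sens, 12), -t)
        key_old = (round(best.j, 12), round(best.sensitivity, 12), -best.cutoff)
        if key_new > key_old:
            best = cand
    return best


def _prop_ci(k: int, n: int, level: float) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return (lo, hi)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> DiagnosticReport:
    """Full confusion-metric panel from the four cells.

    Degenerate margins produce NaN with a flag (or inf for PLR at perfect
    specificity) rather than raising.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    tp, fp, fn, tn = int(tp), int(fp), int(fn), int(tn)
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion table")
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}_undefined")
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    acc = (tp + tn) / n
    if np.isnan(spec):
        plr = float("nan")
        flags.append("plr_undefined")
    elif spec == 1.0:
        plr = float("inf") if sens > 0 else float("nan")
        if sens == 0:
            flags.append("plr_undefined")
    else:
        plr = sens / (1.0 - spec)
    if np.isnan(spec) or spec == 0.0:
        nlr = float("nan")
        flags.append("nlr_undefined")
    else:
        nlr = (1.0 - sens) / spec
    return DiagnosticReport(counts=(tp, fp, fn, tn), sensitivity=sens, specificity=spec,
                            ppv=ppv, npv=npv, accuracy=acc, plr=plr, nlr=nlr, flags=flags)


def predictive_values(sensitivity: float, specificity: float,
                      prevalence: float) -> dict[str, float]:
    """PPV, NPV, PLR, NLR and accuracy from rates via Bayes' rule.

    The rate-based counterpart of :func:`confusion_metrics`, for recomputing
    a published metric panel from its reported sensitivity, specificity and
    positive-group prevalence (no integer cell counts required).
    """
    se, sp, p = float(sensitivity), float(specificity), float(prevalence)
    for name, v in (("sensitivity", se), ("specificity", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} out of [0, 1]: {v}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence out of (0, 1): {p}")
    pos_mass = se * p + (1.0 - sp) * (1.0 - p)
    neg_mass = sp * (1.0 - p) + (1.0 - se) * p
    return {
        "ppv": se * p / pos_mass if pos_mass > 0 else float("nan"),
        "npv": sp * (1.0 - p) / neg_mass if neg_mass > 0 else float("nan"),
        "plr": se / (1.0 - sp) if sp < 1.0 else float("inf"),
        "nlr": (1.0 - se) / sp if sp > 0.0 else float("nan"),
        "accuracy": se * p + sp * (1.0 - p),
    }


def _lr_ci(lr: float, a: int, m1: int, b: int, m0: int, level: float) -> tuple[float, float]:
    """Simel log-method interval for a likelihood ratio a/m1 over b/m0."""
    if not np.isfinite(lr) or lr <= 0 or a == 0 or b == 0:
        return (float("nan"), float("nan"))
    se = math.sqrt(1.0 / a - 1.0 / m1 + 1.0 / b - 1.0 / m0)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (lr * math.exp(-z * se), lr * math.exp(z * se))


def metric_confidence_intervals(report: DiagnosticReport, level: float = 0.95) -> DiagnosticReport:
    """Attach confidence intervals to a :class:`DiagnosticReport`.

    Clopper-Pearson exact for the proportions (one-sided at boundary cells),
    Simel log method for PLR/NLR.
    """
    tp, fp, fn, tn = report.counts
    ci = {
        "sensitivity": _prop_ci(tp, tp + fn, level),
        "specificity": _prop_ci(tn, tn + fp, level),
        "ppv": _prop_ci(tp, tp + fp, level),
        "npv": _prop_ci(tn, tn + fn, level),
        "accuracy": _prop_ci(tp + tn, tp + fp + fn + tn, level),
        "plr": _lr_ci(report.plr, tp, tp + fn, fp, fp + tn, level),
        "nlr": _lr_ci(report.nlr, fn, tp + fn, tn, fp + tn, level),
        "level": level,
    }
    return replace(report, ci=ci)


def evaluate_marker(scores: Sequence[float], labels: Sequence[bool],
                    ci_level: float = 0.95,
                    ci_method: str = "hanley_mcneil") -> tuple[RocResult, DiagnosticReport]:
    """One-stop single-marker evaluation: ROC -> Youden cut-off -> metric panel."""
    roc = empirical_roc(scores, labels, ci_level=ci_level, ci_method=ci_method)
    opt = youden_optimal_cutoff(roc)
    s, y = roc.scores, roc.labels
    call = (s >= opt.cutoff) if roc.direction == "higher_is_positive" else (s <= opt.cutoff)
    tp = int((call & y).sum())
    fp = int((call & ~y).sum())
    fn = int((~call & y).sum())
    tn = int((~call & ~y).sum())
    report = confusion_metrics(tp, fp, fn, tn)
    report = replace(report, cutoff=opt.cutoff, direction=roc.direction)
    report = metric_confidence_intervals(report, level=ci_level)
    _assert_report_identities(report)
    return roc, report


def _assert_report_identities(report: DiagnosticReport) -> None:
    """Internal consistency: accuracy and predictive values obey Bayes' rule."""
    tp, fp, fn, tn = report.counts
    n = tp + fp + fn + tn
    p = (tp + fn) / n
    if not (np.isnan(report.sensitivity) or np.isnan(report.specificity)):
        acc = report.sensitivity * p + report.specificity * (1 - p)
        assert abs(acc - report.accuracy) < 1e-12
    if not np.isnan(report.ppv) and not np.isnan(report.sensitivity) \
            and not np.isnan(report.specificity):
        denom = report.sensitivity * p + (1 - report.specificity) * (1 - p)
        if denom > 0:
            assert abs(report.ppv - report.sensitivity * p / denom) < 1e-12
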