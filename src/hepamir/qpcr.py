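"""Ct-level QC, geNorm reference stability, and 2^-ddCt relative quantification.

The quantification model assumes perfect PCR doubling (efficiency 2), so one
threshold cycle equals one log2 unit of abundance. Normalization divides each
target by the geometric mean of the reference miRNAs — on the Ct scale this is
the arithmetic mean of the reference Cts — and references the result to the
control-group mean, giving levels ``2^-ddCt`` whose control-group geometric
mean is 1 per assay.

Undetected reactions (Ct at or above the detection limit, default 38 cycles)
are treated as missing, not imputed at the threshold, because
censoring-as-value biases fold-changes; an ``impute_at_threshold`` switch
exists for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from hepamir.stats import TestResult, auto_two_sample_test

__all__ = [
    "CtMatrix",
    "QcResult",
    "GenormResult",
    "RelativeLevels",
    "DeltaDeltaCtNormalizer",
    "detection_qc",
    "genorm_rank",
    "normalize_ddct",
    "fold_change_table",
]


@dataclass
class CtMatrix:
    """Subjects x assays matrix of raw qPCR threshold cycles.

    ``ct`` holds raw Ct values in cycles (NaN = not amplified); ``references``
    names the assays playing the normalizer role, all others are targets.
    """

    ct: pd.DataFrame
    references: list[str]

    def __post_init__(self) -> None:
        self.references = list(self.references)
        if self.ct.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        missing = [r for r in self.references if r not in self.ct.columns]
        if missing:
            raise ValueError(f"reference assays absent from Ct matrix: {missing}")
        if len(self.references) < 2:
            raise ValueError("need at least 2 reference assays for the geometric mean")
        vals = self.ct.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        bad = finite[(finite <= 0) | (finite >= 45)]
        if bad.size:
            raise ValueError(f"Ct values must lie in (0, 45); offending values: {bad[:5]}")

    @property
    def targets(self) -> list[str]:
        return [c for c in self.ct.columns if c not in self.references]

    @property
    def subjects(self) -> pd.Index:
        return self.ct.index


@dataclass
class QcResult:
    detected: pd.DataFrame                  # boolean subjects x assays
    detection_fraction: pd.Series           # per assay
    excluded: list[str]                     # target assays failing the detection rule
    filtered_ct: CtMatrix                   # censored values -> NaN, excluded assays dropped
    max_ct: float
    min_detection: float


@dataclass
class GenormResult:
    m_values: pd.Series                     # stability M per assay (lower = more stable)
    ranking: list[str]                      # most stable first
    trace: list[tuple[str, pd.Series]]      # stepwise exclusion: (removed assay, Ms before removal)


@dataclass
class RelativeLevels:
    """Normalized relative abundances (fold vs the control-group mean)."""

    levels: pd.DataFrame                    # subjects x target assays, 2^-ddCt
    delta_ct: pd.DataFrame                  # subjects x target assays, cycles
    control_group: str
    references: list[str] = field(default_factory=list)


def detection_qc(ct: CtMatrix, max_ct: float = 38.0, min_detection: float = 0.9) -> QcResult:
    """Apply the detection rule (Ct < ``max_ct``) and flag poorly detected assays.

    A target assay detected in fewer than ``min_detection`` of subjects is
    excluded from downstream analysis. A *reference* assay failing the rule is
    a hard error — silent loss of the normalizer would corrupt every level.
    """
    values = ct.ct
    detected = values.notna() & (values < max_ct)
    fraction = detected.mean(axis=0)
    failing = fraction[fraction < min_detection].index.tolist()
    bad_refs = [a for a in failing if a in ct.references]
    if bad_refs:
        raise ValueError(
            f"reference assay(s) failed detection QC (fraction < {min_detection}): {bad_refs}")
    excluded = [a for a in failing if a not in ct.references]
    filtered = values.where(detected).drop(columns=excluded)
    return QcResult(
        detected=detected,
        detection_fraction=fraction,
        excluded=excluded,
        filtered_ct=CtMatrix(filtered, ct.references),
        max_ct=max_ct,
        min_detection=min_detection,
    )


def _genorm_m(values: pd.DataFrame) -> pd.Series:
    """Stability M per assay: mean over partner assays of SD(Ct_j - Ct_i).

    With log2 expression = -Ct, the SD across subjects of the pairwise Ct
    difference is exactly the geNorm pairwise variation V_ij. Pairs with
    fewer than 2 complete observations are skipped with a warning.
    """
    assays = list(values.columns)
    m = {}
    for a in assays:
        sds = []
        for b in assays:
            if b == a:
                continue
            diff = (values[b] - values[a]).dropna()
            if len(diff) < 2:
                warnings.warn(f"geNorm pair ({a}, {b}) skipped: "
                              f"<2 complete observations", stacklevel=3)
                continue
            sds.append(float(np.std(diff, ddof=1)))
        if not sds:
            raise ValueError(f"assay {a!r} has no usable pairs for geNorm")
        m[a] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_rank(ct: CtMatrix | pd.DataFrame) -> GenormResult:
    """Rank assays by geNorm expression stability (lower M = more stable).

    The stepwise trace repeatedly removes the least stable assay (highest M)
    and recomputes, down to the final pair, as in the original geNorm scheme.
    """
    values = ct.ct if isinstance(ct, CtMatrix) else ct
    if values.shape[1] < 3:
        raise ValueError(f"geNorm needs >= 3 assays, got {values.shape[1]}")
    m_full = _genorm_m(values)

    trace: list[tuple[str, pd.Series]] = []
    remaining = values.copy()
    removal_order: list[str] = []
    while remaining.shape[1] > 2:
        m_step = _genorm_m(remaining)
        worst = m_step.idxmax()
        trace.append((worst, m_step))
        removal_order.append(worst)
        remaining = remaining.drop(columns=[worst])
    final_pair = list(remaining.columns)
    ranking = final_pair[:]
    ranking += [a for a in reversed(removal_order)]
    # order the final pair by their full-panel M for a deterministic ranking
    ranking[:2] = sorted(final_pair, key=lambda a: (m_full[a], a))
    return GenormResult(m_values=m_full, ranking=ranking, trace=trace)


class DeltaDeltaCtNormalizer:
    """Transformer computing 2^-ddCt levels against a control group.

    ``fit`` learns, per target assay, the control-group mean delta-Ct (target
    Ct minus the arithmetic mean of the reference Cts); ``transform`` turns
    raw Cts of any compatible matrix into fold levels relative to that
    control mean. Follows the fit/transform protocol so it composes with
    pipeline tooling; fitted attributes carry a trailing underscore.
    """

    def __init__(self, references: Sequence[str], control_group: str = "NL"):
        self.references = list(references)
        self.control_group = control_group

    def get_params(self, deep: bool = True) -> dict:
        return {"references": self.references, "control_group": self.control_group}

    def set_params(self, **params) -> "DeltaDeltaCtNormalizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _delta_ct(self, values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
        missing = [r for r in self.references if r not in values.columns]
        if missing:
            raise ValueError(f"reference assays missing from matrix: {missing}")
        ref_mean = values[self.references].mean(axis=1)
        have_refs = values[self.references].notna().all(axis=1)
        if not have_refs.all():
            dropped = values.index[~have_refs].tolist()
            warnings.warn(f"{len(dropped)} subject(s) dropped for missing reference Ct: "
                          f"{dropped[:5]}", stacklevel=3)
        targets = [c for c in values.columns if c not in self.references]
        dct = values.loc[have_refs, targets].sub(ref_mean[have_refs], axis=0)
        return dct, values.index[have_refs]

    def fit(self, ct: CtMatrix | pd.DataFrame, groups: pd.Series) -> "DeltaDeltaCtNormalizer":
        values = ct.ct if isinstance(ct, CtMatrix) else ct
        groups = pd.Series(groups)
        dct, kept = self._delta_ct(values)
        control = dct.loc[[s for s in kept if groups.get(s) == self.control_group]]
        if control.empty:
            raise ValueError(f"control group {self.control_group!r} is empty")
        self.control_delta_ct_ = control.mean(axis=0, skipna=True)
        self.target_assays_ = list(dct.columns)
        return self

    def transform(self, ct: CtMatrix | pd.DataFrame) -> RelativeLevels:
        if not hasattr(self, "control_delta_ct_"):
            raise RuntimeError("normalizer is not fitted")
        values = ct.ct if isinstance(ct, CtMatrix) else ct
        dct, _ = self._delta_ct(values)
        dct = dct[self.target_assays_]
        ddct = dct.sub(self.control_delta_ct_, axis=1)
        levels = np.power(2.0, -ddct)
        return RelativeLevels(levels=levels, delta_ct=dct,
                              control_group=self.control_group,
                              references=list(self.references))

    def fit_transform(self, ct: CtMatrix | pd.DataFrame, groups: pd.Series) -> RelativeLevels:
        return self.fit(ct, groups).transform(ct)


def normalize_ddct(ct: CtMatrix | pd.DataFrame, references: Sequence[str],
                   groups: pd.Series, control_group: str = "NL") -> RelativeLevels:
    """Functional wrapper over :class:`DeltaDeltaCtNormalizer` (fit+transform)."""
    return DeltaDeltaCtNormalizer(references, control_group).fit_transform(ct, groups)


def fold_change_table(levels: RelativeLevels | pd.DataFrame, labels: pd.Series,
                      alpha: float = 0.05, force: Optional[str] = None,
                      min_per_side: int = 2) -> pd.DataFrame:
    """Per-assay fold-change (positive/negative group mean ratio) with p values.

    ``labels`` is a boolean per-subject series (True = the severe side of the
    comparison). The p value comes from the adaptive two-group policy
    (``force`` pins the branch); ``direction`` is induced / repressed at
    ``alpha`` and ``ns`` otherwise.
    """
    lv = levels.levels if isinstance(levels, RelativeLevels) else levels
    labels = pd.Series(labels).reindex(lv.index)
    if labels.isna().any():
        raise ValueError("labels missing for some subjects in the level matrix")
    rows = []
    for assay in lv.columns:
        pos = lv.loc[labels.astype(bool), assay].dropna()
        neg = lv.loc[~labels.astype(bool), assay].dropna()
        if len(pos) < min_per_side or len(neg) < min_per_side:
            warnings.warn(f"assay {assay!r}: comparison skipped "
                          f"(n+={len(pos)}, n-={len(neg)})", stacklevel=2)
            continue
        fc = float(pos.mean() / neg.mean())
        try:
            res: TestResult = auto_two_sample_test(pos, neg, force=force)
        except ValueError:
            warnings.warn(f"assay {assay!r}: test failed, skipped", stacklevel=2)
            continue
        if res.p_value < alpha:
            direction = "induced" if fc > 1.0 else "repressed"
        else:
            direction = "ns"
        rows.append({"assay": assay, "fold_change": fc, "p_value": res.p_value,
                     "test_used": res.test_used, "direction": direction,
                     "n_pos": len(pos), "n_neg": len(neg)})
    return pd.DataFrame(rows).set_index("assay") if rows else pd.DataFrame(
        columns=["fold_change", "p_value", "test_used", "direction", "n_pos", "n_neg"])
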