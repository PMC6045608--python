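"""End-to-end pipeline: QC -> geNorm -> normalize -> severity -> univariate ->
ratios -> ROC -> PLS-DA, with a serialized report bundle.

Each stage writes a diff-able text artifact (TSV or JSON) into the output
directory; the run log records the configuration hash, seed, package version
and per-stage subject/assay counts so two runs with the same seed produce a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

import hepamir
from hepamir.cohort import REFERENCE_ASSAYS
from hepamir.diagnostics import (
    DEFAULT_DENOMINATORS,
    DEFAULT_NUMERATORS,
    build_ratio_features,
    evaluate_marker,
)
from hepamir.plsda import DEFAULT_CLINICAL_PANEL, build_variable_panels, loocv_evaluate
from hepamir.qpcr import CtMatrix, detection_qc, fold_change_table, genorm_rank, normalize_ddct
from hepamir.scoring import score_table

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full analysis pipeline."""

    references: Sequence[str] = REFERENCE_ASSAYS
    control_group: str = "NL"
    max_ct: float = 38.0
    min_detection: float = 0.9
    comparisons: dict = field(default_factory=lambda: {
        "saf_at_risk": "saf_at_risk",
        "nas_definite": "nas_definite",
        "advanced_fibrosis": "advanced_fibrosis",
    })
    ratio_numerators: Sequence[str] = DEFAULT_NUMERATORS
    ratio_denominators: Sequence[str] = DEFAULT_DENOMINATORS
    clinical_panel: Sequence[str] = DEFAULT_CLINICAL_PANEL
    ci_level: float = 0.95
    max_lv: int = 10
    plsda_n_lv: Optional[int] = 2
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level out of (0, 1): {self.ci_level}")
        if len(self.references) < 2:
            raise ValueError("need >= 2 reference assays")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["references"] = list(d["references"])
        d["ratio_numerators"] = list(d["ratio_numerators"])
        d["ratio_denominators"] = list(d["ratio_denominators"])
        d["clinical_panel"] = list(d["clinical_panel"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class StageError(RuntimeError):
    """Failure of a named pipeline stage (partial outputs are retained)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else ("Infinity" if np.isinf(v) else round(v, 10))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _report_dict(report) -> dict:
    return _jsonable({
        "counts": report.counts, "cutoff": report.cutoff,
        "sensitivity": report.sensitivity, "specificity": report.specificity,
        "ppv": report.ppv, "npv": report.npv, "accuracy": report.accuracy,
        "plr": report.plr, "nlr": report.nlr, "direction": report.direction,
        "ci": report.ci, "flags": report.flags,
    })


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame, ct: CtMatrix,
                 outdir) -> dict:
    """Run every stage on a loaded cohort and write the report bundle.

    Returns the in-memory bundle (dict of stage results). Raises
    :class:`StageError` on the first failing stage; artifacts of completed
    stages remain on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    counts_log: dict = {"subjects": int(len(cohort))}

    # -- stage: detection QC ------------------------------------------------
    try:
        missing_refs = [r for r in config.references if r not in ct.ct.columns]
        if missing_refs:
            raise ValueError(f"configured reference assay(s) absent: {missing_refs}")
        qc = detection_qc(CtMatrix(ct.ct, list(config.references)),
                          max_ct=config.max_ct, min_detection=config.min_detection)
    except Exception as exc:
        raise StageError("detection_qc", exc) from exc
    bundle["qc"] = {
        "detection_fraction": qc.detection_fraction.round(6).to_dict(),
        "excluded": qc.excluded,
        "max_ct": qc.max_ct,
        "min_detection": qc.min_detection,
    }
    counts_log["assays_retained"] = int(qc.filtered_ct.ct.shape[1])

    # -- stage: geNorm reference stability ----------------------------------
    try:
        gen = genorm_rank(qc.filtered_ct)
    except Exception as exc:
        raise StageError("genorm", exc) from exc
    bundle["genorm"] = {
        "m_values": gen.m_values.round(8).to_dict(),
        "ranking": gen.ranking,
        "reference_rank": {r: int(gen.ranking.index(r)) + 1 for r in config.references},
    }
    (outdir / "qc.json").write_text(
        json.dumps(_jsonable({"qc": bundle["qc"], "genorm": bundle["genorm"]}), indent=1))

    # -- stage: normalization ------------------------------------------------
    try:
        levels = normalize_ddct(qc.filtered_ct, config.references,
                                cohort["group"], config.control_group)
    except Exception as exc:
        raise StageError("normalize", exc) from exc
    levels.levels.round(8).to_csv(outdir / "levels.tsv", sep="\t",
                                  index_label="subject_id", na_rep="")
    counts_log["subjects_normalized"] = int(len(levels.levels))

    # -- stage: severity scoring --------------------------------------------
    try:
        scores = score_table(cohort)
        scores["nas_definite"] = scores["nas"] >= 5
    except Exception as exc:
        raise StageError("severity", exc) from exc
    scores.round(6).to_csv(outdir / "severity.tsv", sep="\t",
                           index_label="subject_id", na_rep="")

    # -- stage: univariate fold-changes ---------------------------------------
    fold_changes = {}
    for name, label_col in config.comparisons.items():
        if label_col in scores.columns:
            labels = scores[label_col]
        elif label_col in cohort.columns:
            labels = cohort[label_col]
        else:
            raise StageError("fold_change",
                             ValueError(f"comparison {name!r}: no column {label_col!r}"))
        labels = labels.reindex(levels.levels.index).fillna(False).astype(bool)
        if labels.sum() < 2 or (~labels).sum() < 2:
            warnings.warn(f"comparison {name!r} skipped: degenerate labels")
            continue
        tab = fold_change_table(levels, labels)
        tab.round(8).to_csv(outdir / f"foldchange_{name}.tsv", sep="\t", na_rep="")
        fold_changes[name] = tab
    bundle["fold_changes"] = fold_changes

    # -- stage: ratio features + per-marker diagnostics ----------------------
    try:
        available_num = [a for a in config.ratio_numerators if a in levels.levels.columns]
        available_den = [a for a in config.ratio_denominators if a in levels.levels.columns]
        ratios = build_ratio_features(levels, available_num, available_den)
    except Exception as exc:
        raise StageError("ratios", exc) from exc
    ratios.round(8).to_csv(outdir / "ratios.tsv", sep="\t",
                           index_label="subject_id", na_rep="")

    markers = pd.concat([levels.levels, ratios], axis=1)
    if "fib4" in scores.columns:
        markers = pd.concat([markers, scores[["fib4", "apri", "bard", "nfs"]],
                             cohort[["ast", "alt"]]], axis=1)
    diag: dict = {}
    for name, label_col in config.comparisons.items():
        if name not in fold_changes and label_col not in scores.columns \
                and label_col not in cohort.columns:
            continue
        labels = (scores[label_col] if label_col in scores.columns
                  else cohort[label_col])
        labels = labels.reindex(markers.index).fillna(False).astype(bool)
        if labels.nunique() < 2:
            continue
        diag[name] = {}
        for marker in markers.columns:
            s = markers[marker]
            ok = s.notna()
            if ok.sum() < 4 or labels[ok].nunique() < 2:
                continue
            roc, report = evaluate_marker(s[ok], labels[ok], ci_level=config.ci_level)
            diag[name][marker] = {
                "auroc": round(roc.auroc, 6), "auroc_ci": _jsonable(roc.auroc_ci),
                "direction": roc.direction, **_report_dict(report),
            }
    (outdir / "diagnostics.json").write_text(json.dumps(_jsonable(diag), indent=1))
    bundle["diagnostics"] = diag

    # -- stage: PLS-DA cross-validation ---------------------------------------
    try:
        panels = build_variable_panels(cohort, levels.levels, ratios,
                                       clinical_vars=[v for v in config.clinical_panel
                                                      if v in cohort.columns])
    except Exception as exc:
        raise StageError("panels", exc) from exc
    plsda_rows = []
    for comp_name, label_col in config.comparisons.items():
        labels = (scores[label_col] if label_col in scores.columns
                  else cohort[label_col]).reindex(cohort.index).fillna(False).astype(bool)
        if labels.nunique() < 2:
            continue
        for panel_name, X in panels.items():
            perf = loocv_evaluate(X, labels.astype(float), n_lv=config.plsda_n_lv,
                                  max_lv=config.max_lv, ci_level=config.ci_level,
                                  panel=panel_name)
            plsda_rows.append({
                "comparison": comp_name, "panel": panel_name,
                "variables": X.shape[1], "n_lv": perf.n_lv,
                "cv_auroc": round(perf.auroc, 6),
                "sensitivity": round(perf.report.sensitivity, 6),
                "specificity": round(perf.report.specificity, 6),
                "plr": round(perf.report.plr, 6) if np.isfinite(perf.report.plr) else "inf",
                "nlr": round(perf.report.nlr, 6),
                "accuracy": round(perf.report.accuracy, 6),
            })
    plsda_tab = pd.DataFrame(plsda_rows)
    plsda_tab.to_csv(outdir / "plsda.tsv", sep="\t", index=False, na_rep="")
    bundle["plsda"] = plsda_tab

    # -- run log ---------------------------------------------------------------
    cfg = config.to_dict()
    log = {
        "package_version": hepamir.__version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "seed": config.seed,
        "counts": counts_log,
    }
    (outdir / "run_log.json").write_text(json.dumps(_jsonable(log), indent=1))
    bundle["log"] = log
    return bundle
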