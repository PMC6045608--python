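"""PLS-DA (NIPALS) with leave-one-out cross-validation.

The classifier regresses a centered {0, 1} class vector on autoscaled
predictors through PLS1 latent variables and calls class 1 when the
continuous prediction crosses 0.5 (the midpoint of the class codes; a Youden
threshold on cross-validated scores is available as an option in
:func:`loocv_evaluate`). With as many latent variables as the predictor rank,
the fit coincides with ordinary least squares — a property the test suite
asserts.

Cross-validation is leakage-free: autoscaling constants and median imputation
values are recomputed inside every training fold, so the held-out subject
never influences its own predictor scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hepamir.diagnostics import (
    DiagnosticReport,
    confusion_metrics,
    empirical_roc,
    metric_confidence_intervals,
    youden_optimal_cutoff,
)

__all__ = [
    "PLSDAClassifier",
    "CvPerformance",
    "loocv_select_lv",
    "loocv_evaluate",
    "build_variable_panels",
    "DEFAULT_CLINICAL_PANEL",
]

# 16 laboratory/anthropometric variables forming the default clinical panel
DEFAULT_CLINICAL_PANEL = (
    "age", "bmi", "glucose", "triglycerides", "cholesterol", "hdl", "ldl",
    "bilirubin", "albumin", "platelets", "alt", "ast", "ggt", "alp",
    "ferritin", "hb",
)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {arr.shape}")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


class PLSDAClassifier:
    """Binary PLS-DA classifier trained by the NIPALS PLS1 algorithm.

    Parameters
    ----------
    n_lv : int
        Number of latent variables.
    scale : bool
        Autoscale predictors to unit variance (always centered). Sample
        standard deviations (ddof=1) are used.

    Attributes (after ``fit``)
    --------------------------
    x_mean_, x_scale_ : per-variable standardization constants
    weights_, x_loadings_ : (p, n_lv) weight and loading matrices
    y_loadings_ : (n_lv,) regression loadings of the class vector
    coef_ : (p,) regression vector on the standardized scale
    coef_path_ : (p, n_lv) coefficients after 1..n_lv components
    scores_ : (n, n_lv) latent-variable scores (mutually orthogonal)
    intercept_ : class-code mean added back at prediction
    """

    def __init__(self, n_lv: int = 2, scale: bool = True):
        self.n_lv = n_lv
        self.scale = scale

    # -- sklearn-style parameter plumbing ---------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_lv": self.n_lv, "scale": self.scale}

    def set_params(self, **params) -> "PLSDAClassifier":
        for key, value in params.items():
            if key not in ("n_lv", "scale"):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y) -> "PLSDAClassifier":
        Xm, names = _as_matrix(X)
        yv = np.asarray(y, dtype=float).ravel()
        if len(yv) != Xm.shape[0]:
            raise ValueError("X and y length mismatch")
        classes = np.unique(yv)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError(f"y must be coded {{0, 1}}, got classes {classes}")
        if len(classes) < 2:
            warnings.warn("single-class training fold: model degenerates to the "
                          "class-code mean", stacklevel=2)
        if np.isnan(Xm).any():
            raise ValueError("X contains missing values; impute before fitting")
        n, p = Xm.shape
        max_feasible = min(n - 1, p)
        if not (1 <= self.n_lv <= max_feasible):
            raise ValueError(f"n_lv={self.n_lv} out of [1, {max_feasible}] "
                             f"for n={n}, p={p}")

        self.x_mean_ = Xm.mean(axis=0)
        sd = Xm.std(axis=0, ddof=1) if n > 1 else np.ones(p)
        if self.scale:
            zero = np.flatnonzero(np.ptp(Xm, axis=0) == 0.0)
            if zero.size:
                raise ValueError(f"zero-variance variable(s): "
                                 f"{[names[i] for i in zero]}")
            self.x_scale_ = sd.copy()
        else:
            self.x_scale_ = np.ones(p)
        self.var_names_ = names
        self._nipals(( Xm - self.x_mean_) / self.x_scale_, yv)
        return self

    def _nipals(self, X0: np.ndarray, y: np.ndarray) -> None:
        """PLS1 NIPALS with deflation; fills weight/loading/coefficient paths."""
        n, p = X0.shape
        self.intercept_ = float(y.mean())
        Xd = X0.copy()
        yd = y - self.intercept_
        W = np.zeros((p, self.n_lv))
        P = np.zeros((p, self.n_lv))
        q = np.zeros(self.n_lv)
        T = np.zeros((n, self.n_lv))
        actual = 0
        for a in range(self.n_lv):
            wv = Xd.T @ yd
            norm = np.linalg.norm(wv)
            if norm <= 1e-12 * max(1.0, np.abs(yd).sum()):
                warnings.warn(f"NIPALS stopped at {actual} component(s): residual "
                              "covariance exhausted", stacklevel=3)
                break
            wv /= norm
            t = Xd @ wv
            tt = float(t @ t)
            if tt <= 1e-300:
                break
            pv = Xd.T @ t / tt
            qa = float(yd @ t / tt)
            Xd -= np.outer(t, pv)
            yd = yd - t * qa
            W[:, a], P[:, a], q[a], T[:, a] = wv, pv, qa, t
            actual += 1
        self.n_lv_fitted_ = actual if actual else 1
        W, P, q, T = W[:, :self.n_lv_fitted_], P[:, :self.n_lv_fitted_], \
            q[:self.n_lv_fitted_], T[:, :self.n_lv_fitted_]
        self.weights_, self.x_loadings_, self.y_loadings_, self.scores_ = W, P, q, T
        # coefficient path: B_a = W_a (P_a' W_a)^-1 q_a for a = 1..n_lv
        self.coef_path_ = np.zeros((X0.shape[1], self.n_lv_fitted_))
        PtW = P.T @ W
        for a in range(self.n_lv_fitted_):
            sub = PtW[: a + 1, : a + 1]
            self.coef_path_[:, a] = W[:, : a + 1] @ np.linalg.solve(sub, q[: a + 1])
        self.coef_ = self.coef_path_[:, -1]

    # -- prediction --------------------------------------------------------
    def _standardize(self, X) -> np.ndarray:
        Xm, names = _as_matrix(X)
        if Xm.shape[1] != len(self.var_names_):
            raise ValueError(f"variable count mismatch: model has "
                             f"{len(self.var_names_)}, got {Xm.shape[1]}")
        if isinstance(X, pd.DataFrame) and names != self.var_names_:
            raise ValueError("variable names differ from training variables")
        return (Xm - self.x_mean_) / self.x_scale_

    def decision_function(self, X, n_lv: Optional[int] = None) -> np.ndarray:
        """Continuous class score (~0 for class 0, ~1 for class 1)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        coef = self.coef_ if n_lv is None else self.coef_path_[:, n_lv - 1]
        return self._standardize(X) @ coef + self.intercept_

    def predict(self, X, n_lv: Optional[int] = None) -> np.ndarray:
        return (self.decision_function(X, n_lv=n_lv) >= 0.5).astype(int)


@dataclass
class CvPerformance:
    """Out-of-fold performance of a PLS-DA model under LOO-CV."""

    cv_scores: np.ndarray
    labels: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]
    report: DiagnosticReport
    n_lv: int
    panel: Optional[str] = None
    lv_error_curve: Optional[np.ndarray] = None


def _prepare_fold(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Train-fold median imputation applied to both partitions."""
    if np.isnan(X_train).any() or np.isnan(X_test).any():
        med = np.nanmedian(X_train, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        X_train = np.where(np.isnan(X_train), med, X_train)
        X_test = np.where(np.isnan(X_test), med, X_test)
    return X_train, X_test


def _fold_scores(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """LOO out-of-fold continuous scores for every component count 1..max_lv.

    Returns an (n, max_lv) array. Autoscaling, imputation and the NIPALS fit
    are all redone inside each fold. Fold-internal zero-variance variables are
    left centered at zero (scale 1) instead of failing the fold.

    Pooled scores use the overall class prevalence as intercept rather than
    each fold's training mean: the fold mean is anti-correlated with the
    held-out label (a training set missing a positive has a lower mean), which
    would bias pooled null CV AUROC below 0.5. The prevalence is a single
    constant, so it carries no subject-level information.
    """
    n, p = X.shape
    prevalence = float(y.mean())
    out = np.full((n, max_lv), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Xte = _prepare_fold(X[mask], X[[i]])
        ytr = y[mask]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd = np.where(np.ptp(Xtr, axis=0) == 0.0, 1.0, sd)
        Xtr_s = (Xtr - mean) / sd
        Xte_s = (Xte - mean) / sd

        model = PLSDAClassifier(n_lv=max_lv)
        model.x_mean_, model.x_scale_ = np.zeros(p), np.ones(p)
        model.var_names_ = [f"x{j}" for j in range(p)]
        model._nipals(Xtr_s, ytr)
        for a in range(1, max_lv + 1):
            coef = model.coef_path_[:, min(a, model.n_lv_fitted_) - 1]
            out[i, a - 1] = float((Xte_s @ coef)[0]) + prevalence
    return out


def loocv_select_lv(X, y, max_lv: int = 10) -> tuple[int, np.ndarray]:
    """Select the latent-variable count minimizing LOO misclassifications.

    Returns ``(best_n_lv, error_curve)`` where ``error_curve[a-1]`` is the
    number of misclassified held-out subjects with ``a`` components. Ties go
    to the smallest count (parsimony).
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if n < 10:
        raise ValueError(f"LOO-CV selection needs n >= 10, got {n}")
    feasible = min(max_lv, n - 2, p)
    if feasible < max_lv:
        warnings.warn(f"max_lv reduced from {max_lv} to {feasible} "
                      f"(n={n}, p={p})", stacklevel=2)
    scores = _fold_scores(Xm, yv, feasible)
    errors = ((scores >= 0.5).astype(float) != yv[:, None]).sum(axis=0)
    best = int(np.argmin(errors)) + 1
    return best, errors


def loocv_evaluate(X, y, n_lv: Optional[int] = None, max_lv: int = 10,
                   threshold: str = "midpoint", ci_level: float = 0.95,
                   panel: Optional[str] = None) -> CvPerformance:
    """Generalization performance under LOO-CV.

    Every subject is predicted exactly once by a model trained without it;
    AUROC and the confusion panel are computed only from those out-of-fold
    scores. ``threshold="midpoint"`` calls class 1 at score >= 0.5;
    ``"youden"`` instead places the cut-off maximizing J on the CV scores.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    error_curve = None
    if n_lv is None:
        n_lv, error_curve = loocv_select_lv(Xm, yv, max_lv=max_lv)
    feasible = min(n_lv, Xm.shape[0] - 2, Xm.shape[1])
    cv_scores = _fold_scores(Xm, yv, feasible)[:, feasible - 1]

    roc = empirical_roc(cv_scores, yv.astype(bool), direction="higher_is_positive",
                        ci_level=ci_level)
    if threshold == "midpoint":
        cutoff = 0.5
    elif threshold == "youden":
        cutoff = youden_optimal_cutoff(roc).cutoff
    else:
        raise ValueError(f"unknown threshold {threshold!r}")
    call = cv_scores >= cutoff
    ybool = yv.astype(bool)
    report = confusion_metrics(int((call & ybool).sum()), int((call & ~ybool).sum()),
                               int((~call & ybool).sum()), int((~call & ~ybool).sum()))
    report = metric_confidence_intervals(report, level=ci_level)
    return CvPerformance(cv_scores=cv_scores, labels=yv, auroc=roc.auroc,
                         auroc_ci=roc.auroc_ci, report=report, n_lv=feasible,
                         panel=panel, lv_error_curve=error_curve)


def build_variable_panels(cohort: pd.DataFrame, levels: pd.DataFrame,
                          ratios: pd.DataFrame,
                          clinical_vars: Sequence[str] = DEFAULT_CLINICAL_PANEL,
                          mirna_assays: Optional[Sequence[str]] = None,
                          ratio_names: Optional[Sequence[str]] = None
                          ) -> dict[str, pd.DataFrame]:
    """Assemble the clinical / miRNA / combined predictor panels.

    Defaults: 16 clinical variables, all detected miRNAs plus all but one of
    the default induced/repressed ratios (16 + 17 = 33), and their union (49).
    """
    missing = [v for v in clinical_vars if v not in cohort.columns]
    if missing:
        raise ValueError(f"clinical panel variables absent from cohort: {missing}")
    clinical = cohort.loc[:, list(clinical_vars)].astype(float)

    if mirna_assays is None:
        mirna_assays = list(levels.columns)
    missing = [a for a in mirna_assays if a not in levels.columns]
    if missing:
        raise ValueError(f"miRNA panel assays absent from levels: {missing}")
    if ratio_names is None:
        ratio_names = [r for r in ratios.columns if r != "miR-21/16"]
    missing = [r for r in ratio_names if r not in ratios.columns]
    if missing:
        raise ValueError(f"ratio panel features absent: {missing}")

    mirna = pd.concat([levels.loc[:, list(mirna_assays)],
                       ratios.loc[:, list(ratio_names)]], axis=1)
    combined = pd.concat([clinical, mirna], axis=1)
    if combined.columns.has_duplicates:
        raise ValueError("duplicate variable names across panels")
    return {"clinical": clinical, "mirna": mirna, "combined": combined}
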