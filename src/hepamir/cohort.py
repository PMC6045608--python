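"""Synthetic NAFLD / DILI cohort generator.

Emulates a three-group biopsy-proven NAFLD cohort (17 normal-liver controls,
25 NAFL, 50 NASH) plus a drug-induced liver injury comparison group (17 NL vs
17 DILI): clinical variables drawn from per-group normal distributions
truncated at physiologic floors, histology grades drawn from per-group
categorical marginals with resampling until the diagnostic constraints hold
(NASH requires steatosis >= 1, ballooning >= 1 and lobular inflammation >= 1;
NAFL requires SAF activity < 2), and raw qPCR Ct values generated as

    Ct = base_ct - log2_effect(group) + Normal(0, ct_noise_sd),

censored to missing at the detection limit (default 38 cycles). Reference
miRNAs carry no group effect, so normalized fold-changes recover
``2**log2_effect`` exactly in the noise-free limit.

What this generator does *not* emulate: covariance between clinical
variables, joint histology structure beyond the diagnostic constraints, and
any longitudinal or assay-plate effects — the defaults encode only the
published group marginals, so passing tests certify the pipeline's
statistical machinery, not clinical realism.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from hepamir.qpcr import CtMatrix

__all__ = [
    "GroupSpec",
    "MiRnaEffectSpec",
    "CohortSpec",
    "default_spec",
    "default_dili_spec",
    "generate_cohort",
    "generate_dili_cohort",
]

HISTOLOGY_FEATURES = {
    "steatosis_grade": 3,
    "ballooning": 2,
    "lobular_inflammation": 2,
    "fibrosis_stage": 4,
}

# variables that are physically strictly positive (normal draws redrawn at <= 0)
_POSITIVE_FLOOR = {
    "age", "bmi", "waist", "glucose", "triglycerides", "cholesterol", "hdl",
    "ldl", "bilirubin", "albumin", "platelets", "alt", "ast", "ggt", "alp",
    "prothrombin", "hb", "transferrin_sat", "ferritin", "hba1c", "insulin",
}


@dataclass
class GroupSpec:
    """One cohort group: size, clinical (mean, sd) pairs, histology marginals."""

    name: str
    n: int
    clinical_params: dict[str, tuple[float, float]]
    histology_probs: dict[str, dict[int, float]]
    male_fraction: float = 0.5
    dili_flag: bool = False

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.name}: n must be >= 0, got {self.n}")
        for var, (mu, sd) in self.clinical_params.items():
            if sd < 0:
                raise ValueError(f"group {self.name}: sd < 0 for {var!r}")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError(f"group {self.name}: male_fraction out of [0, 1]")
        for feat, probs in self.histology_probs.items():
            if feat not in HISTOLOGY_FEATURES:
                raise ValueError(f"group {self.name}: unknown histology feature {feat!r}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {self.name}: histology_probs[{feat!r}] "
                                 f"sums to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"group {self.name}: negative probability in {feat!r}")
            hi = HISTOLOGY_FEATURES[feat]
            if any(not (0 <= g <= hi) for g in probs):
                raise ValueError(f"group {self.name}: grade out of range in {feat!r}")
        if self.name == "NL":
            for feat, probs in self.histology_probs.items():
                if abs(probs.get(0, 0.0) - 1.0) > 1e-9:
                    raise ValueError(f"NL group must put mass 1 on grade 0 for {feat!r}")


@dataclass
class MiRnaEffectSpec:
    """Generative model for one qPCR assay."""

    assay: str
    base_ct: float                      # mean Ct in the NL group, cycles
    log2_effect: dict[str, float] = field(default_factory=dict)  # group -> shift
    ct_noise_sd: float = 1.0            # residual Ct SD, cycles
    is_reference: bool = False
    dropout_ct: float = 38.0            # censoring threshold, cycles

    def validate(self) -> None:
        if not (15.0 <= self.base_ct <= 40.0):
            raise ValueError(f"assay {self.assay}: base_ct out of [15, 40]")
        if self.ct_noise_sd < 0:
            raise ValueError(f"assay {self.assay}: ct_noise_sd < 0")
        if self.is_reference and any(e != 0.0 for e in self.log2_effect.values()):
            raise ValueError(f"assay {self.assay}: reference assays must have "
                             f"zero log2_effect in every group")

    def effect(self, group: str) -> float:
        return float(self.log2_effect.get(group, 0.0))


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    mirnas: list[MiRnaEffectSpec]
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("spec needs at least one group")
        n_refs = sum(m.is_reference for m in self.mirnas)
        if n_refs < 2:
            raise ValueError(f"spec needs >= 2 reference assays, got {n_refs}")
        for g in self.groups:
            g.validate()
        for m in self.mirnas:
            m.validate()

    @property
    def references(self) -> list[str]:
        return [m.assay for m in self.mirnas if m.is_reference]

    # -- YAML-friendly round-trip -----------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "groups": [
                {
                    "name": g.name, "n": g.n, "male_fraction": g.male_fraction,
                    "dili_flag": g.dili_flag,
                    "clinical_params": {k: [float(v[0]), float(v[1])]
                                        for k, v in g.clinical_params.items()},
                    "histology_probs": {k: {int(gr): float(p) for gr, p in d.items()}
                                        for k, d in g.histology_probs.items()},
                }
                for g in self.groups
            ],
            "mirnas": [
                {
                    "assay": m.assay, "base_ct": m.base_ct,
                    "log2_effect": dict(m.log2_effect),
                    "ct_noise_sd": m.ct_noise_sd, "is_reference": m.is_reference,
                    "dropout_ct": m.dropout_ct,
                }
                for m in self.mirnas
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortSpec":
        groups = [
            GroupSpec(
                name=g["name"], n=int(g["n"]),
                clinical_params={k: (float(v[0]), float(v[1]))
                                 for k, v in g["clinical_params"].items()},
                histology_probs={k: {int(gr): float(p) for gr, p in d.items()}
                                 for k, d in g["histology_probs"].items()},
                male_fraction=float(g.get("male_fraction", 0.5)),
                dili_flag=bool(g.get("dili_flag", False)),
            )
            for g in data["groups"]
        ]
        mirnas = [
            MiRnaEffectSpec(
                assay=m["assay"], base_ct=float(m["base_ct"]),
                log2_effect={k: float(v) for k, v in m.get("log2_effect", {}).items()},
                ct_noise_sd=float(m.get("ct_noise_sd", 1.0)),
                is_reference=bool(m.get("is_reference", False)),
                dropout_ct=float(m.get("dropout_ct", 38.0)),
            )
            for m in data["mirnas"]
        ]
        return cls(groups=groups, mirnas=mirnas, seed=int(data.get("seed", 0)))


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

_NL_CLINICAL = {
    "age": (42.9, 9.3), "bmi": (26.2, 3.6), "glucose": (89.9, 10.7),
    "triglycerides": (106.7, 36.3), "cholesterol": (203.7, 37.4),
    "hdl": (55.0, 18.2), "ldl": (128.1, 34.7), "bilirubin": (0.6, 0.2),
    "albumin": (4.5, 0.5), "platelets": (245.2, 75.1), "alt": (29.8, 16.7),
    "ast": (26.0, 8.8), "ggt": (50.8, 51.4), "alp": (86.1, 32.7),
    "prothrombin": (14.6, 2.1), "hb": (13.9, 0.9),
    "transferrin_sat": (27.2, 9.6), "ferritin": (66.8, 54.7),
    # fasting insulin was not determined for controls in the source table;
    # a normal fasting range is assumed so HOMA-IR stays computable
    "insulin": (8.0, 4.0),
}

_NAFL_CLINICAL = {
    "age": (51.6, 10.4), "bmi": (29.6, 5.2), "waist": (99.8, 17.0),
    "glucose": (118.1, 39.7), "triglycerides": (126.3, 66.3),
    "cholesterol": (202.6, 43.6), "hdl": (52.5, 11.2), "ldl": (123.7, 41.5),
    "bilirubin": (0.7, 0.3), "albumin": (4.6, 0.3), "platelets": (260.1, 74.2),
    "alt": (51.8, 32.1), "ast": (36.0, 15.1), "ggt": (134.0, 144.8),
    "alp": (106.4, 48.2), "prothrombin": (14.1, 1.4), "hb": (14.7, 1.2),
    "transferrin_sat": (26.8, 11.7), "ferritin": (113.1, 58.7),
    "hba1c": (6.4, 1.4), "insulin": (17.4, 11.1),
}

_NASH_CLINICAL = {
    "age": (57.4, 10.4), "bmi": (32.4, 4.6), "waist": (107.5, 11.1),
    "glucose": (126.7, 62.3), "triglycerides": (190.8, 104.4),
    "cholesterol": (199.0, 39.2), "hdl": (45.6, 13.4), "ldl": (122.9, 33.7),
    "bilirubin": (0.6, 0.3), "albumin": (4.6, 0.3), "platelets": (218.4, 66.5),
    "alt": (64.7, 52.6), "ast": (54.6, 35.4), "ggt": (122.8, 128.1),
    "alp": (95.4, 35.5), "prothrombin": (14.0, 1.6), "hb": (14.4, 1.1),
    "transferrin_sat": (28.1, 11.0), "ferritin": (283.8, 325.7),
    "hba1c": (6.5, 1.3), "insulin": (32.5, 37.3),
}

_DILI_CLINICAL = {
    "age": (53.3, 19.3), "bmi": (24.6, 2.7), "glucose": (91.6, 14.2),
    "triglycerides": (211.9, 138.2), "cholesterol": (188.9, 76.9),
    "bilirubin": (11.2, 15.4), "albumin": (3.8, 0.5), "platelets": (341.0, 125.0),
    "alt": (94.6, 48.7), "ast": (72.7, 39.8), "ggt": (347.8, 275.2),
    "alp": (320.6, 184.9), "hb": (13.1, 1.9),
}

_ALL_ZERO_HIST = {feat: {0: 1.0} for feat in HISTOLOGY_FEATURES}

_NAFL_HIST = {
    "steatosis_grade": {1: 0.80, 2: 0.12, 3: 0.08},
    "ballooning": {0: 0.72, 1: 0.28},
    "lobular_inflammation": {0: 0.52, 1: 0.48},
    "fibrosis_stage": {0: 0.84, 1: 0.16},
}

_NASH_HIST = {
    "steatosis_grade": {1: 0.08, 2: 0.46, 3: 0.46},
    "ballooning": {1: 0.40, 2: 0.60},
    "lobular_inflammation": {0: 0.02, 1: 0.70, 2: 0.28},
    "fibrosis_stage": {0: 0.08, 1: 0.18, 2: 0.16, 3: 0.32, 4: 0.26},
}

# base Cts placed in the observed serum band (cycles ~24-37; the two assays
# at/above the detection limit emulate the non-amplifying candidates)
_BASE_CT = {
    "miR-34a": 36.0, "miR-27b": 31.0, "miR-22": 31.0, "miR-122": 29.0,
    "miR-192": 30.0, "miR-21": 29.0, "miR-30c": 33.0, "miR-16": 24.0,
    "miR-197": 34.0, "miR-451a": 25.0, "miR-663a": 35.0, "miR-146b": 32.0,
    "miR-331": 34.0, "miR-181d": 35.0, "miR-375": 35.0, "miR-29a": 33.0,
    "miR-99a": 39.0, "miR-1290": 39.5,
}

INDUCED_NAFLD = ("miR-34a", "miR-27b", "miR-22", "miR-122", "miR-192", "miR-21")
REPRESSED_NAFLD = ("miR-30c", "miR-16", "miR-197")
INDUCED_DILI = ("miR-34a", "miR-122", "miR-21", "miR-451a", "miR-663a",
                "miR-146b", "miR-331", "miR-197")
REPRESSED_DILI = ("miR-16",)

REFERENCE_ASSAYS = ("miR-15a", "miR-25")
_REF_BASE_CT = {"miR-15a": 27.0, "miR-25": 28.0}


def _mirna_panel(effect_of, ct_noise_sd: float, ref_noise_sd: float,
                 dropout_ct: float) -> list[MiRnaEffectSpec]:
    panel = [
        MiRnaEffectSpec(assay=a, base_ct=ct, log2_effect=effect_of(a),
                        ct_noise_sd=ct_noise_sd, dropout_ct=dropout_ct)
        for a, ct in _BASE_CT.items()
    ]
    panel += [
        MiRnaEffectSpec(assay=a, base_ct=_REF_BASE_CT[a], log2_effect={},
                        ct_noise_sd=ref_noise_sd, is_reference=True,
                        dropout_ct=dropout_ct)
        for a in REFERENCE_ASSAYS
    ]
    return panel


def default_spec(effect_nash: float = 1.0, effect_nafl: float = 0.3,
                 ct_noise_sd: float = 1.0, ref_noise_sd: float = 0.5,
                 dropout_ct: float = 38.0, seed: int = 0) -> CohortSpec:
    """Default three-group NAFLD cohort spec (17 NL / 25 NAFL / 50 NASH).

    Clinical (mean, sd) pairs and histology marginals follow the published
    cohort characteristics; miRNA effects are +/-``effect_nash`` log2 units in
    NASH and +/-``effect_nafl`` in NAFL with the validated directions
    (induced: 34a, 27b, 22, 122, 192, 21; repressed: 30c, 16, 197).
    """

    def effect_of(assay: str) -> dict[str, float]:
        if assay in INDUCED_NAFLD:
            return {"NAFL": effect_nafl, "NASH": effect_nash}
        if assay in REPRESSED_NAFLD:
            return {"NAFL": -effect_nafl, "NASH": -effect_nash}
        return {}

    groups = [
        GroupSpec("NL", 17, dict(_NL_CLINICAL), copy.deepcopy(_ALL_ZERO_HIST),
                  male_fraction=0.412),
        GroupSpec("NAFL", 25, dict(_NAFL_CLINICAL), copy.deepcopy(_NAFL_HIST),
                  male_fraction=0.44),
        GroupSpec("NASH", 50, dict(_NASH_CLINICAL), copy.deepcopy(_NASH_HIST),
                  male_fraction=0.38),
    ]
    spec = CohortSpec(groups=groups,
                      mirnas=_mirna_panel(effect_of, ct_noise_sd, ref_noise_sd, dropout_ct),
                      seed=seed)
    spec.validate()
    return spec


def default_dili_spec(effect: float = 1.0, ct_noise_sd: float = 1.0,
                      ref_noise_sd: float = 0.5, dropout_ct: float = 38.0,
                      seed: int = 0) -> CohortSpec:
    """Default NL (17) vs DILI (17) cohort spec.

    DILI directions: induced 34a, 122, 21, 451a, 663a, 146b, 331, 197;
    decreased 16; unchanged 27b, 192, 22, 30c.
    """

    def effect_of(assay: str) -> dict[str, float]:
        if assay in INDUCED_DILI:
            return {"DILI": effect}
        if assay in REPRESSED_DILI:
            return {"DILI": -effect}
        return {}

    groups = [
        GroupSpec("NL", 17, dict(_NL_CLINICAL), copy.deepcopy(_ALL_ZERO_HIST),
                  male_fraction=0.412),
        GroupSpec("DILI", 17, dict(_DILI_CLINICAL), copy.deepcopy(_ALL_ZERO_HIST),
                  male_fraction=0.647, dili_flag=True),
    ]
    spec = CohortSpec(groups=groups,
                      mirnas=_mirna_panel(effect_of, ct_noise_sd, ref_noise_sd, dropout_ct),
                      seed=seed)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 1000


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Normal draw redrawn while <= 0 (physiologic floor)."""
    if sd == 0.0:
        return mu
    for _ in range(_MAX_REDRAWS):
        x = rng.normal(mu, sd)
        if x > 0:
            return float(x)
    return abs(float(rng.normal(mu, sd)))  # pathological (mean << 0) fallback


def _draw_histology(rng: np.random.Generator, group: GroupSpec) -> dict[str, int]:
    """Independent categorical draws, resampled until group constraints hold.

    NASH: steatosis >= 1, ballooning >= 1 and lobular inflammation >= 1 (so
    SAF activity >= 2). NAFL: SAF activity < 2.
    """
    feats = list(HISTOLOGY_FEATURES)
    grades_p = {}
    for feat in feats:
        probs = group.histology_probs.get(feat, {0: 1.0})
        grades_p[feat] = (np.array(sorted(probs)), np.array([probs[g] for g in sorted(probs)]))
    for _ in range(_MAX_REDRAWS):
        draw = {feat: int(rng.choice(g, p=p)) for feat, (g, p) in grades_p.items()}
        act = draw["ballooning"] + draw["lobular_inflammation"]
        if group.name == "NASH":
            if draw["steatosis_grade"] >= 1 and draw["ballooning"] >= 1 \
                    and draw["lobular_inflammation"] >= 1:
                return draw
        elif group.name == "NAFL":
            if act < 2:
                return draw
        else:
            return draw
    raise RuntimeError(f"could not satisfy histology constraints for group {group.name}")


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None
                    ) -> tuple[pd.DataFrame, CtMatrix]:
    """Draw one cohort: per-subject clinical/histology table plus raw Ct matrix.

    Identical ``(spec, seed)`` give bit-identical output. ``seed=None`` uses
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    clinical_vars: list[str] = []
    for g in spec.groups:
        for v in g.clinical_params:
            if v not in clinical_vars:
                clinical_vars.append(v)

    rows = []
    sid = 0
    for group in spec.groups:
        for _ in range(group.n):
            sid += 1
            row: dict = {"subject_id": f"S{sid:03d}", "group": group.name,
                         "dili": group.dili_flag}
            row["sex"] = "M" if rng.random() < group.male_fraction else "F"
            for var in clinical_vars:
                if var in group.clinical_params:
                    mu, sd = group.clinical_params[var]
                    row[var] = (_truncated_normal(rng, mu, sd)
                                if var in _POSITIVE_FLOOR else float(rng.normal(mu, sd)))
                else:
                    row[var] = np.nan
            row["diabetes_or_ifg"] = bool(row.get("glucose", 0.0) >= 100.0)
            row.update(_draw_histology(rng, group))
            rows.append(row)
    cohort = pd.DataFrame(rows).set_index("subject_id")

    ct_cols = {}
    groups_arr = cohort["group"].to_numpy()
    n_total = len(cohort)
    for m in spec.mirnas:
        shift = np.array([m.effect(g) for g in groups_arr])
        ct = m.base_ct - shift + rng.normal(0.0, m.ct_noise_sd, size=n_total)
        ct = np.where(ct >= m.dropout_ct, np.nan, ct)
        ct = np.clip(ct, 0.01, 44.99)  # keep draws inside the physical Ct domain
        ct_cols[m.assay] = ct
    ct_df = pd.DataFrame(ct_cols, index=cohort.index)
    return cohort, CtMatrix(ct_df, references=spec.references)


def generate_dili_cohort(spec: Optional[CohortSpec] = None, seed: Optional[int] = None
                         ) -> tuple[pd.DataFrame, CtMatrix]:
    """Generate the NL vs DILI cohort (defaults to :func:`default_dili_spec`)."""
    if spec is None:
        spec = default_dili_spec()
    if not any(g.dili_flag for g in spec.groups):
        raise ValueError("DILI cohort spec must contain a dili-flagged group")
    return generate_cohort(spec, seed=seed)
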