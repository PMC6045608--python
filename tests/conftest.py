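import warnings

import numpy as np
import pytest

from hepamir import default_spec, generate_cohort
from hepamir.cohort import CohortSpec, GroupSpec, MiRnaEffectSpec
from hepamir.qpcr import detection_qc, normalize_ddct


@pytest.fixture(scope="session")
def nafld_cohort():
    """One default synthetic NAFLD cohort (17 NL / 25 NAFL / 50 NASH)."""
    spec = default_spec()
    cohort, ct = generate_cohort(spec, seed=7)
    return spec, cohort, ct


@pytest.fixture(scope="session")
def nafld_levels(nafld_cohort):
    """QC-filtered, control-referenced relative levels for the default cohort."""
    _, cohort, ct = nafld_cohort
    qc = detection_qc(ct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        levels = normalize_ddct(qc.filtered_ct, ct.references, cohort["group"])
    return cohort, qc, levels


def make_noise_free_spec(effects=None, n_nl=4, n_nash=4):
    """Tiny deterministic two-group spec: zero Ct noise, configurable effects."""
    effects = effects or {}
    clin = {"age": (50.0, 0.0), "ast": (30.0, 0.0), "alt": (30.0, 0.0),
            "platelets": (250.0, 0.0), "glucose": (90.0, 0.0)}
    groups = [
        GroupSpec("NL", n_nl, dict(clin), {f: {0: 1.0} for f in
                  ("steatosis_grade", "ballooning", "lobular_inflammation",
                   "fibrosis_stage")}),
        GroupSpec("NASH", n_nash, dict(clin), {
            "steatosis_grade": {2: 1.0}, "ballooning": {1: 1.0},
            "lobular_inflammation": {1: 1.0}, "fibrosis_stage": {3: 1.0}}),
    ]
    mirnas = [
        MiRnaEffectSpec("miR-122", 29.0, {"NASH": effects.get("miR-122", 0.0)},
                        ct_noise_sd=0.0),
        MiRnaEffectSpec("miR-197", 34.0, {"NASH": effects.get("miR-197", 0.0)},
                        ct_noise_sd=0.0),
        MiRnaEffectSpec("miR-15a", 27.0, {}, ct_noise_sd=0.0, is_reference=True),
        MiRnaEffectSpec("miR-25", 28.0, {}, ct_noise_sd=0.0, is_reference=True),
    ]
    return CohortSpec(groups=groups, mirnas=mirnas, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
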