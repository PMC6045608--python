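"""Detection QC, geNorm stability and 2^-ddCt normalization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hepamir.cohort import generate_cohort
from hepamir.qpcr import (
    CtMatrix,
    detection_qc,
    fold_change_table,
    genorm_rank,
    normalize_ddct,
)

SUBJECTS = [f"S{i:03d}" for i in range(1, 93)]


def _ct(df_dict, refs=("ref1", "ref2"), index=None):
    df = pd.DataFrame(df_dict, index=index)
    return CtMatrix(df, references=list(refs))


def make_matrix(n=92, seed=0):
    rng = np.random.default_rng(seed)
    data = {
        "miR-A": rng.normal(30, 1, n),
        "miR-B": rng.normal(33, 1, n),
        "ref1": rng.normal(27, 0.3, n),
        "ref2": rng.normal(28, 0.3, n),
    }
    return _ct(data, index=SUBJECTS[:n])


class TestDetectionQc:
    def test_all_detected_no_exclusions(self):
        ct = _ct({"miR-A": [30.0] * 10, "ref1": [27.0] * 10, "ref2": [28.0] * 10},
                 index=SUBJECTS[:10])
        qc = detection_qc(ct)
        assert qc.excluded == []
        assert (qc.detection_fraction == 1.0).all()

    def test_fully_missing_assay_excluded(self):
        ct = make_matrix()
        values = ct.ct.copy()
        values["miR-dead"] = np.nan
        qc = detection_qc(CtMatrix(values, ct.references))
        assert "miR-dead" in qc.excluded
        assert qc.detection_fraction["miR-dead"] == 0.0
        assert "miR-dead" not in qc.filtered_ct.ct.columns

    def test_threshold_arithmetic_at_min_detection(self):
        ct = make_matrix()
        values = ct.ct.copy()
        values["miR-ok"] = 30.0
        values.iloc[:7, values.columns.get_loc("miR-ok")] = np.nan   # 85/92 = 0.924
        values["miR-bad"] = 30.0
        values.iloc[:12, values.columns.get_loc("miR-bad")] = np.nan  # 80/92 = 0.870
        qc = detection_qc(CtMatrix(values, ct.references))
        assert "miR-ok" not in qc.excluded
        assert "miR-bad" in qc.excluded

    def test_high_ct_counts_as_undetected(self):
        ct = make_matrix()
        values = ct.ct.copy()
        values["miR-late"] = 39.0  # above the 38-cycle confidence limit
        qc = detection_qc(CtMatrix(values, ct.references))
        assert "miR-late" in qc.excluded

    def test_failing_reference_is_hard_error(self):
        ct = make_matrix()
        values = ct.ct.copy()
        values.loc[values.index[:20], "ref1"] = np.nan
        with pytest.raises(ValueError, match="ref1"):
            detection_qc(CtMatrix(values, ct.references))

    def test_idempotent(self):
        ct = make_matrix()
        values = ct.ct.copy()
        values.iloc[:5, 0] = 39.5
        first = detection_qc(CtMatrix(values, ct.references))
        second = detection_qc(first.filtered_ct)
        assert second.excluded == []
        pd.testing.assert_frame_equal(first.filtered_ct.ct, second.filtered_ct.ct)


class TestGenorm:
    def test_proportional_assays_have_zero_pairwise_sd(self):
        n = 8
        base = np.linspace(25, 32, n)
        ct = pd.DataFrame({"a": base, "b": base + 2.0, "c": base[::-1]})
        res = genorm_rank(ct)
        # a and b differ by a constant: their mutual pair contributes SD 0,
        # so both M values equal half... i.e. only the c-pair SD counts
        sd_ac = np.std(ct["c"] - ct["a"], ddof=1)
        assert res.m_values["a"] == pytest.approx(sd_ac / 2, abs=1e-12)
        assert res.m_values["b"] == pytest.approx(sd_ac / 2, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        ct = pd.DataFrame(rng.normal(30, 2, size=(6, 4)), columns=list("abcd"))
        res = genorm_rank(ct)
        for i, a in enumerate(ct.columns):
            sds = [np.std(ct[b] - ct[a], ddof=1) for b in ct.columns if b != a]
            assert res.m_values[a] == pytest.approx(np.mean(sds), abs=1e-10)

    def test_permutation_equivariance_and_offset_invariance(self, rng):
        ct = pd.DataFrame(rng.normal(30, 2, size=(10, 5)), columns=list("abcde"))
        res = genorm_rank(ct)
        shuffled = genorm_rank(ct[["d", "b", "e", "a", "c"]])
        for a in ct.columns:
            assert shuffled.m_values[a] == pytest.approx(res.m_values[a], abs=1e-12)
        offset = genorm_rank(ct + np.array([1.0, -2.0, 0.5, 3.0, 0.0]))
        for a in ct.columns:
            assert offset.m_values[a] == pytest.approx(res.m_values[a], abs=1e-10)

    def test_stepwise_trace_reaches_final_pair(self, rng):
        ct = pd.DataFrame(rng.normal(30, 1, size=(12, 5)), columns=list("abcde"))
        res = genorm_rank(ct)
        assert len(res.trace) == 3
        assert len(res.ranking) == 5

    def test_designated_references_rank_top_two(self):
        """Low-noise reference assays win the stability ranking (simulation)."""
        from hepamir.cohort import default_spec

        spec = default_spec(ct_noise_sd=1.0, ref_noise_sd=0.1)
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            _, ct = generate_cohort(spec, seed=seed)
            qc = detection_qc(ct)
            res = genorm_rank(qc.filtered_ct)
            if set(res.ranking[:2]) == {"miR-15a", "miR-25"}:
                wins += 1
        assert wins / n_rep >= 0.95


class TestNormalize:
    def test_hand_worked_example(self):
        ct = _ct({"target": [30.0, 30.0, 28.0], "ref1": [25.0] * 3, "ref2": [27.0] * 3},
                 refs=("ref1", "ref2"), index=["c1", "c2", "case"])
        groups = pd.Series({"c1": "NL", "c2": "NL", "case": "NASH"})
        levels = normalize_ddct(ct, ["ref1", "ref2"], groups, "NL")
        # control dCt = 30 - 26 = 4; case dCt = 2; ddCt = -2 -> level 4
        assert levels.levels.loc["case", "target"] == pytest.approx(4.0)
        assert levels.levels.loc["c1", "target"] == pytest.approx(1.0)

    def test_ddct_defining_property(self):
        ct = _ct({"t": [30.0, 29.0, 32.0], "ref1": [25.0] * 3, "ref2": [25.0] * 3},
                 index=["c1", "x2", "x4"])
        groups = pd.Series({"c1": "NL", "x2": "A", "x4": "B"})
        levels = normalize_ddct(ct, ["ref1", "ref2"], groups, "NL")
        assert levels.levels.loc["x2", "t"] == pytest.approx(2.0)    # ddCt = -1
        assert levels.levels.loc["x4", "t"] == pytest.approx(0.25)   # ddCt = +2

    def test_control_geometric_mean_is_one(self, nafld_levels):
        cohort, _, levels = nafld_levels
        ctrl = levels.levels.loc[cohort.loc[levels.levels.index, "group"] == "NL"]
        geo = np.exp(np.log(ctrl).mean(axis=0))
        assert np.allclose(geo, 1.0, atol=1e-9)

    def test_global_subject_shift_invariance(self, nafld_levels):
        """A per-subject additive Ct offset (efficiency shift) cancels out."""
        cohort, qc, levels = nafld_levels
        shifted = qc.filtered_ct.ct.add(
            pd.Series(np.linspace(-1, 1, len(qc.filtered_ct.ct)),
                      index=qc.filtered_ct.ct.index), axis=0)
        lv2 = normalize_ddct(CtMatrix(shifted, qc.filtered_ct.references),
                             qc.filtered_ct.references, cohort["group"], "NL")
        pd.testing.assert_frame_equal(levels.levels, lv2.levels, atol=1e-9, rtol=0)

    def test_subject_missing_reference_dropped_with_warning(self):
        ct_df = pd.DataFrame({"t": [30.0] * 4, "ref1": [25.0, 25.0, np.nan, 25.0],
                              "ref2": [26.0] * 4}, index=["a", "b", "c", "d"])
        groups = pd.Series({"a": "NL", "b": "NL", "c": "NASH", "d": "NASH"})
        with pytest.warns(UserWarning, match="missing reference"):
            levels = normalize_ddct(CtMatrix(ct_df, ["ref1", "ref2"]),
                                    ["ref1", "ref2"], groups, "NL")
        assert "c" not in levels.levels.index

    def test_empty_control_group_errors(self):
        ct = _ct({"t": [30.0] * 3, "ref1": [25.0] * 3, "ref2": [26.0] * 3},
                 index=["a", "b", "c"])
        groups = pd.Series({"a": "NASH", "b": "NASH", "c": "NASH"})
        with pytest.raises(ValueError, match="control group"):
            normalize_ddct(ct, ["ref1", "ref2"], groups, "NL")


class TestFoldChange:
    def test_identical_groups_are_null(self):
        lv = pd.DataFrame({"t": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                          index=list("abcdef"))
        labels = pd.Series([True, True, True, False, False, False], index=list("abcdef"))
        tab = fold_change_table(lv, labels)
        assert tab.loc["t", "fold_change"] == pytest.approx(1.0)
        assert tab.loc["t", "direction"] == "ns"

    def test_zero_noise_effect_recovers_two_fold(self):
        from conftest import make_noise_free_spec

        spec = make_noise_free_spec(effects={"miR-122": 1.0})
        cohort, ct = generate_cohort(spec, seed=0)
        levels = normalize_ddct(ct, spec.references, cohort["group"], "NL")
        labels = cohort["group"].eq("NASH")
        tab = fold_change_table(levels, labels)
        assert tab.loc["miR-122", "fold_change"] == pytest.approx(2.0)
        assert tab.loc["miR-122", "direction"] == "induced"
        assert tab.loc["miR-197", "fold_change"] == pytest.approx(1.0)

    def test_degenerate_group_skipped(self):
        lv = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        labels = pd.Series([True, False, False, False], index=list("abcd"))
        with pytest.warns(UserWarning, match="skipped"):
            tab = fold_change_table(lv, labels)
        assert tab.empty
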