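"""Tests for the repeated stratified CV harness, fusion, and summaries."""

import numpy as np
import pandas as pd
import pytest

from fairdx import (GroupFixture, RateFixtureConfig, SensitiveAttributeSpec,
                    compare_distributions, fuse_majority, fuse_weighted,
                    generate_prediction_fixture, run_repeated_cv,
                    summarize_fairness)


def _member(keys, preds, scores, name="m"):
    df = keys.copy()
    df["y_pred"] = preds
    df["score"] = scores
    df["classifier"] = name
    return df


@pytest.fixture
def keys():
    return pd.DataFrame({
        "subject_id": ["s1", "s2", "s3"],
        "repeat": 1, "fold": 1, "mitigation": "none",
        "y_true": [1, 0, 1],
        "grp": ["a", "a", "b"],
    })


@pytest.fixture(scope="module")
def cv_table(demo_cohort):
    subjects, features = demo_cohort
    labels = subjects.set_index("subject_id")["clinical_label"]
    groups = subjects.set_index("subject_id")[["gender", "race"]]
    return run_repeated_cv(features, labels, groups, n_repeats=2, n_folds=5,
                           seed=17)


class TestRepeatedCV:
    def test_each_subject_tested_once_per_repeat(self, cv_table):
        per_clf = cv_table.groupby("classifier").size()
        assert (per_clf == 146).all()  # 73 subjects x 2 repeats
        for (_, rep), part in cv_table.groupby(["classifier", "repeat"]):
            assert part["subject_id"].is_unique
            assert len(part) == 73

    def test_folds_partition_and_stratify(self, cv_table, demo_cohort):
        subjects, _ = demo_cohort
        n_pos = subjects["clinical_label"].sum()
        clf = cv_table["classifier"].iloc[0]
        part = cv_table[cv_table["classifier"] == clf]
        for rep, rp in part.groupby("repeat"):
            folds = rp.groupby("fold")["y_true"].agg(["size", "sum"])
            assert folds["size"].sum() == 73
            # pigeonhole: positives per fold within 1 of exact proportionality
            lo, hi = np.floor(n_pos / 5), np.ceil(n_pos / 5)
            assert folds["sum"].between(lo, hi).all()

    def test_reproducible_from_master_seed(self, demo_cohort):
        subjects, features = demo_cohort
        labels = subjects.set_index("subject_id")["clinical_label"]
        groups = subjects.set_index("subject_id")[["gender"]]
        kw = dict(n_repeats=1, n_folds=5, seed=23, mitigate="gender")
        a = run_repeated_cv(features, labels, groups, **kw)
        b = run_repeated_cv(features, labels, groups, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_mitigated_variant_emitted_alongside_unmitigated(self, demo_cohort):
        subjects, features = demo_cohort
        labels = subjects.set_index("subject_id")["clinical_label"]
        groups = subjects.set_index("subject_id")[["gender"]]
        tab = run_repeated_cv({"facial": features["facial"]}, labels, groups,
                              n_repeats=1, n_folds=5, seed=3,
                              mitigate="gender")
        assert set(tab["mitigation"]) == {"none", "gender"}
        none = tab[tab["mitigation"] == "none"]
        mit = tab[tab["mitigation"] == "gender"]
        assert len(none) == len(mit) == 73
        merged = none.merge(mit, on="subject_id", suffixes=("_n", "_m"))
        assert (merged["score_n"] == merged["score_m"]).all()

    def test_scores_are_probabilities(self, cv_table):
        assert cv_table["score"].between(0, 1).all()
        assert ((cv_table.loc[cv_table["mitigation"] == "none", "score"] > 0.5)
                == (cv_table.loc[cv_table["mitigation"] == "none",
                                 "y_pred"] == 1)).all()

    def test_invalid_protocol_rejected(self, demo_cohort):
        subjects, features = demo_cohort
        labels = subjects.set_index("subject_id")["clinical_label"]
        groups = subjects.set_index("subject_id")[["gender"]]
        with pytest.raises(ValueError):
            run_repeated_cv(features, labels, groups, n_repeats=0)
        with pytest.raises(ValueError, match="mitigation attribute"):
            run_repeated_cv(features, labels, groups, n_repeats=1,
                            mitigate="shoe_size")


class TestFusion:
    def test_strict_majority(self, keys):
        members = [_member(keys, [1, 1, 0], [0.9, 0.8, 0.1], "m1"),
                   _member(keys, [1, 0, 0], [0.7, 0.2, 0.3], "m2"),
                   _member(keys, [0, 1, 0], [0.4, 0.6, 0.2], "m3")]
        fused = fuse_majority(members).sort_values("subject_id")
        assert fused["y_pred"].tolist() == [1, 1, 0]
        assert fused["classifier"].unique().tolist() == ["majority_vote"]

    def test_tie_broken_by_weighted_rule(self, keys):
        members = [_member(keys, [1, 1, 1], [0.9, 0.8, 0.9], "m1"),
                   _member(keys, [0, 0, 1], [0.5, 0.1, 0.8], "m2")]
        fused = fuse_majority(members).sort_values("subject_id")
        # s1: votes split, mean score 0.7 > 0.5 -> 1
        # s2: votes split, mean score 0.45 <= 0.5 -> 0; s3 unanimous 1
        assert fused["y_pred"].tolist() == [1, 0, 1]

    def test_unanimous_members_pass_through(self, keys):
        members = [_member(keys, [1, 0, 1], [0.8, 0.2, 0.7], n)
                   for n in ("m1", "m2", "m3")]
        fused = fuse_majority(members).sort_values("subject_id")
        assert fused["y_pred"].tolist() == [1, 0, 1]

    def test_weighted_mean_score_rule(self, keys):
        members = [_member(keys, [1, 0, 0], [0.6, 0.5, 0.2], "m1"),
                   _member(keys, [0, 0, 0], [0.4, 0.5, 0.3], "m2"),
                   _member(keys, [1, 0, 1], [0.9, 0.5, 0.9], "m3")]
        fused = fuse_weighted(members).sort_values("subject_id")
        assert fused["score"].tolist() == pytest.approx(
            [0.6333333333, 0.5, 0.4666666667])
        # strict inequality at 0.5: all-0.5 scores predict negative
        assert fused["y_pred"].tolist() == [1, 0, 0]

    def test_single_member_weighted_is_identity(self, keys):
        m = _member(keys, [1, 0, 1], [0.8, 0.3, 0.6], "m1")
        fused = fuse_weighted([m]).sort_values("subject_id")
        assert fused["score"].tolist() == [0.8, 0.3, 0.6]
        assert fused["y_pred"].tolist() == [1, 0, 1]

    def test_weighted_fusion_of_copies_is_that_classifier(self, keys):
        m = _member(keys, [1, 0, 1], [0.8, 0.3, 0.6], "m1")
        copies = [m.assign(classifier=f"c{i}") for i in range(3)]
        fused = fuse_weighted(copies).sort_values("subject_id")
        assert fused["score"].tolist() == pytest.approx([0.8, 0.3, 0.6])
        assert fused["y_pred"].tolist() == [1, 0, 1]

    def test_misaligned_tables_error_names_keys(self, keys):
        m1 = _member(keys, [1, 0, 1], [0.8, 0.3, 0.6], "m1")
        m2 = _member(keys.assign(subject_id=["s1", "s2", "s9"]),
                     [1, 0, 1], [0.8, 0.3, 0.6], "m2")
        with pytest.raises(ValueError, match="misaligned"):
            fuse_majority([m1, m2])

    def test_out_of_range_scores_rejected(self, keys):
        m1 = _member(keys, [1, 0, 1], [0.8, 0.3, 0.6], "m1")
        m2 = _member(keys, [1, 0, 1], [1.2, 0.3, 0.6], "m2")
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            fuse_weighted([m1, m2])


class TestSummarizeFairness:
    spec = SensitiveAttributeSpec("group", ("a", "b"), "a", min_group_size=1)

    def _fixture_table(self, tpr_a=0.8, fpr_a=0.2, tpr_b=0.8, fpr_b=0.2,
                       n_repeats=3):
        cfg = RateFixtureConfig(groups=[
            GroupFixture("a", 10, 10, tpr_a, fpr_a),
            GroupFixture("b", 10, 10, tpr_b, fpr_b)], seed=2)
        tab = generate_prediction_fixture(cfg, n_repeats=n_repeats)
        tab["classifier"] = "fix"
        tab["mitigation"] = "none"
        return tab

    def test_equal_rates_give_unit_ratios_every_repeat(self):
        report = summarize_fairness(self._fixture_table(), [self.spec])
        ratios = report.values.query("metric != 'macro_f1'")
        assert len(ratios) == 12  # 4 metrics x 3 repeats
        assert (ratios["value"] == 1.0).all()

    def test_per_repeat_values_match_fixture_targets(self):
        report = summarize_fairness(
            self._fixture_table(tpr_b=0.6, fpr_b=0.4), [self.spec])
        eor = report.values.query("metric == 'eor_overall'")["value"]
        expected = min(0.601 / 0.801, 0.201 / 0.401)
        assert eor.tolist() == pytest.approx([expected] * 3, abs=1e-12)

    def test_single_repeat_summary_equals_value(self):
        report = summarize_fairness(
            self._fixture_table(tpr_b=0.7, n_repeats=1), [self.spec])
        summary = report.summary.query("metric == 'eor_overall'").iloc[0]
        value = report.values.query("metric == 'eor_overall'")["value"].iloc[0]
        assert summary["median"] == pytest.approx(value)
        assert summary["iqr"] == pytest.approx(0.0)
        assert summary["n"] == 1

    def test_per_group_macro_f1_rows_present(self):
        report = summarize_fairness(self._fixture_table(), [self.spec])
        f1 = report.values.query("metric == 'macro_f1'")
        assert set(f1["group"]) == {"", "a", "b"}

    def test_missing_attribute_errors(self):
        tab = self._fixture_table()
        spec = SensitiveAttributeSpec("absent", ("a", "b"), "a")
        with pytest.raises(ValueError):
            summarize_fairness(tab, [spec])

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_fairness(pd.DataFrame(), [self.spec])


class TestCompareDistributions:
    def test_identical_samples_not_significant(self):
        res = compare_distributions([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.5 and not res.significant

    def test_separated_triples_exact_p(self):
        res = compare_distributions([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1)
        assert not res.significant

    def test_symmetry_under_swap(self):
        a, b = [0.2, 0.5, 0.9, 0.4], [0.7, 0.6, 0.85]
        assert compare_distributions(a, b).p_value == pytest.approx(
            compare_distributions(b, a).p_value)
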