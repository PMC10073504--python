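"""Selection methods: paired transitions, discrete-state tests, redundancy, PCA."""

import numpy as np
import pandas as pd
import pytest

import transfeat as tf
from transfeat.selection import (AnnotationTable, ComparisonDesign,
                                 FeatureDecision, SelectionResult,
                                 discrete_select, paired_samples, pca_reduce,
                                 redundancy_filter, selection_from_annotations,
                                 transition_select)
from transfeat.simulate import synthetic_feature_matrix, transition_shift_rate


def make_fm(rng, n_subjects=20, label_means=None, **kw):
    return synthetic_feature_matrix(n_subjects, label_means or {}, rng, **kw)


class TestPairedSamples:
    def test_one_pair_per_subject(self, rng):
        fm = make_fm(rng, n_subjects=17)
        before, after = paired_samples(fm, ("neutral", "negative"),
                                       features=["HR_ECG"])
        assert len(before) == len(after) == 17

    def test_identical_segments_give_zero_diffs(self, rng):
        fm = make_fm(rng, n_subjects=10, between_sd=0.0, within_sd=0.0)
        before, after = paired_samples(fm, ("neutral", "negative"),
                                       features=["HR_ECG"])
        assert np.allclose(after["HR_ECG"] - before["HR_ECG"], 0.0)

    def test_planted_shift_recovered(self, rng):
        fm = make_fm(rng, n_subjects=60, label_means={"negative": 5.0},
                     between_sd=0.5, within_sd=0.1)
        before, after = paired_samples(fm, ("neutral", "negative"),
                                       features=["HR_ECG"])
        assert (after["HR_ECG"] - before["HR_ECG"]).mean() == pytest.approx(5.0, abs=0.5)


class TestTransitionSelect:
    def test_null_feature_not_selected(self, rng):
        fm = make_fm(rng, n_subjects=15, between_sd=0.0, within_sd=0.0)
        res = transition_select(fm, features=["HR_ECG"])
        assert res.final_subset == []
        assert all(p == 1.0 for p in res.decisions["HR_ECG"].p_values.values())

    def test_planted_effect_selected(self, rng):
        fm = make_fm(rng, n_subjects=40,
                     label_means={"negative": 3.0, "positive": 2.0},
                     between_sd=0.5, within_sd=0.1)
        res = transition_select(fm, features=["HR_ECG"])
        assert res.final_subset == ["HR_ECG"]

    def test_power_above_99_percent_at_one_sd_shift(self):
        rate = transition_shift_rate(85, 1.0, n_reps=200, seed=31)
        assert rate > 0.99

    def test_type_one_error_controlled(self):
        rate = transition_shift_rate(85, 0.0, n_reps=500, seed=32)
        assert rate <= 0.05

    def test_alpha_monotonicity(self, rng):
        fm = make_fm(rng, n_subjects=30,
                     label_means={"negative": 0.8, "positive": 0.5},
                     between_sd=1.0, within_sd=0.2)
        strict = set(transition_select(fm, alpha=0.01,
                                       features=["HR_ECG"]).significant_features)
        loose = set(transition_select(fm, alpha=0.05,
                                      features=["HR_ECG"]).significant_features)
        assert strict <= loose

    def test_needs_six_subjects(self, rng):
        fm = make_fm(rng, n_subjects=4)
        with pytest.raises(ValueError):
            transition_select(fm, features=["HR_ECG"])


class TestDiscreteSelect:
    def test_identical_states_not_selected(self, rng):
        fm = make_fm(rng, n_subjects=12, between_sd=0.0, within_sd=0.0)
        res = discrete_select(fm, features=["HR_ECG"])
        assert res.final_subset == []

    def test_monotone_state_effect_selected(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            fm = make_fm(r, n_subjects=40,
                         label_means={"neutral": 0.0, "negative": 1.0,
                                      "positive": 2.0},
                         between_sd=0.0, within_sd=0.3)
            res = discrete_select(fm, features=["HR_ECG"])
            hits += res.final_subset == ["HR_ECG"]
        assert hits / reps > 0.95

    def test_null_type_one_rate(self):
        hits = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(5000 + seed)
            fm = make_fm(r, n_subjects=20, between_sd=1.0, within_sd=0.2)
            res = discrete_select(fm, features=["HR_ECG"],
                                  apply_redundancy=False)
            hits += bool(res.significant_features)
        assert hits / reps <= 0.05


class TestTransitionVsDiscreteSensitivity:
    def test_transition_method_wins_on_transient_effects(self):
        """Effects that fade within a state: equal neutral/positive means kill
        the discrete method's third comparison while every transition still
        straddles a change."""
        m3_hits = m1_hits = 0
        reps = 100
        for seed in range(reps):
            r = np.random.default_rng(7000 + seed)
            fm = make_fm(r, n_subjects=30,
                         label_means={"neutral": 0.5, "negative": 1.0,
                                      "positive": 0.5, "relax": 0.0},
                         between_sd=0.3, within_sd=0.1)
            m3 = transition_select(fm, features=["HR_ECG"], apply_redundancy=False)
            m1 = discrete_select(fm, features=["HR_ECG"], apply_redundancy=False)
            m3_hits += bool(m3.significant_features)
            m1_hits += bool(m1.significant_features)
        assert m3_hits > m1_hits


class TestRedundancyFilter:
    @staticmethod
    def result_for(features):
        return SelectionResult("M3", 0.05,
                               {f: FeatureDecision(f, significant=True)
                                for f in features}, [])

    def test_linear_copy_discarded(self, rng):
        a = rng.standard_normal(200)
        fm = pd.DataFrame({"MEANRR_ECG": a, "SDNN_ECG": 2 * a + 1})
        res = redundancy_filter(self.result_for(["MEANRR_ECG", "SDNN_ECG"]), fm)
        assert res.final_subset == ["MEANRR_ECG"]
        d = res.decisions["SDNN_ECG"]
        assert d.discarded_redundant and d.partner == "MEANRR_ECG"
        assert d.correlation == pytest.approx(1.0)

    def test_order_dependence_keep_first(self, rng):
        a = rng.standard_normal(200)
        # registry order decides the survivor: MEANRR_ECG precedes SDNN_ECG
        fm = pd.DataFrame({"SDNN_ECG": a, "MEANRR_ECG": 2 * a})
        res = redundancy_filter(self.result_for(["SDNN_ECG", "MEANRR_ECG"]), fm)
        assert res.final_subset == ["MEANRR_ECG"]

    def test_independent_features_all_kept(self, rng):
        fm = pd.DataFrame({f: rng.standard_normal(400)
                           for f in ["MEANRR_ECG", "SDNN_ECG", "RMSSD_ECG"]})
        res = redundancy_filter(self.result_for(list(fm.columns)), fm)
        assert set(res.final_subset) == set(fm.columns)

    def test_idempotent(self, rng):
        cols = ["MEANRR_ECG", "SDNN_ECG", "RMSSD_ECG", "NN50_ECG"]
        base = rng.standard_normal((300, 2))
        fm = pd.DataFrame({
            "MEANRR_ECG": base[:, 0],
            "SDNN_ECG": 0.97 * base[:, 0] + 0.05 * rng.standard_normal(300),
            "RMSSD_ECG": base[:, 1],
            "NN50_ECG": rng.standard_normal(300),
        })
        first = redundancy_filter(self.result_for(cols), fm).final_subset
        res2 = self.result_for(first)
        second = redundancy_filter(res2, fm[first]).final_subset
        assert second == first

    def test_constant_feature_kept_and_flagged(self, rng):
        fm = pd.DataFrame({"MEANRR_ECG": np.ones(100),
                           "SDNN_ECG": rng.standard_normal(100)})
        res = redundancy_filter(self.result_for(list(fm.columns)), fm)
        assert "MEANRR_ECG" in res.final_subset
        assert res.decisions["MEANRR_ECG"].constant


class TestPCA:
    def test_total_dimension_is_17(self, short_fm):
        reduced, report = pca_reduce(short_fm)
        pcs = [c for c in reduced.columns if c.startswith("PC")]
        assert len(pcs) == 17
        assert sum(len(r["explained_variance_ratio"]) for r in report.values()) == 17

    def test_explained_variance_ratios_valid(self, short_fm):
        _, report = pca_reduce(short_fm)
        for r in report.values():
            evr = np.array(r["explained_variance_ratio"])
            assert np.all(np.diff(evr) <= 1e-12)    # non-increasing
            assert evr.sum() <= 1.0 + 1e-9

    def test_full_rank_reconstructs(self, rng):
        n = 120
        fm = pd.DataFrame({f: rng.standard_normal(n)
                           for f in tf.registry.group_columns("BVP")})
        reduced, report = pca_reduce(fm, {"BVP": 12})
        Z = reduced[[c for c in reduced.columns if c.startswith("PC")]].to_numpy()
        load = np.array(report["BVP"]["loadings"])
        X = fm.to_numpy()
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(Z @ load, Xz, atol=1e-8)

    def test_duplicated_column_shared_variance(self, rng):
        a = rng.standard_normal(300)
        cols = tf.registry.group_columns("GSR")
        data = {c: rng.standard_normal(300) for c in cols}
        data[cols[0]] = a
        data[cols[1]] = a.copy()
        _, report = pca_reduce(pd.DataFrame(data), {"GSR": 2})
        # duplicated pair loads one component with their full shared variance
        evr = report["GSR"]["explained_variance_ratio"]
        assert evr[0] >= 2.0 / 12 - 0.05

    def test_too_many_components_rejected(self, rng):
        fm = pd.DataFrame({f: rng.standard_normal(50)
                           for f in tf.registry.group_columns("ECG")})
        with pytest.raises(ValueError):
            pca_reduce(fm, {"ECG": 16})


class TestAnnotations:
    def test_discrete_method_counts(self):
        tbl = AnnotationTable.bundled()
        out = selection_from_annotations(tbl, "M1")
        assert out["preliminary_count"] == 33
        assert out["discarded_count"] == 11
        assert out["final_count"] == 22

    def test_transition_method_counts(self):
        tbl = AnnotationTable.bundled()
        out = selection_from_annotations(tbl, "M3")
        assert out["preliminary_count"] == 17
        assert out["final_count"] == 13
        assert out["per_signal_final"] == {"ECG": 5, "BVP": 4, "GSR": 4}

    def test_all_dash_table(self):
        rows = pd.DataFrame({"signal": ["ECG"] * 3,
                             "feature": ["A", "B", "C"],
                             "method": ["M1"] * 3,
                             "marker": ["—"] * 3})
        out = selection_from_annotations(AnnotationTable(rows), "M1")
        assert (out["preliminary_count"], out["discarded_count"],
                out["final_count"]) == (0, 0, 0)

    def test_unknown_marker_rejected(self):
        rows = pd.DataFrame({"signal": ["ECG"], "feature": ["A"],
                             "method": ["M1"], "marker": ["?"]})
        with pytest.raises(ValueError):
            AnnotationTable(rows)


class TestDesignValidation:
    def test_mode_mismatch_rejected(self, rng):
        fm = make_fm(rng, n_subjects=10)
        with pytest.raises(ValueError):
            transition_select(fm, design=ComparisonDesign.discrete_default())

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            ComparisonDesign("transition", ())
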