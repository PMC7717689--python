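"""Subject-disjoint splits, exhaustive panel search, metrics, Hoeffding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hierde.classify import (
    CLASSIFIER_NAMES,
    PanelSearch,
    SplitPlan,
    evaluate,
    hoeffding_bound,
    make_classifier,
    panel_search,
    split_by_subject,
)
from hierde.synthetic import CohortDesign, generate_metadata


def _panel_matrix(meta, seed=0, separating=False):
    """10-gene panel matrix; optionally plant a perfectly separating gene."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(0, 0.1, size=(len(meta), 10)),
                     index=meta["sample_id"].to_numpy(),
                     columns=[f"G{i:02d}" for i in range(10)])
    if separating:
        X["G03"] = np.where(meta["diagnosis"].to_numpy() == "AD", 5.0, 0.0) \
            + rng.normal(0, 0.1, len(meta))
    return X


class TestSplitBySubject:
    def test_subject_disjoint_and_exhaustive(self, cohort_meta):
        plan = split_by_subject(cohort_meta, 0.7, seed=1)
        tr = set(plan.train_samples)
        te = set(plan.test_samples)
        assert not tr & te
        assert tr | te == set(cohort_meta["sample_id"])
        subj = cohort_meta.set_index("sample_id")["subject_id"]
        assert not set(subj[list(tr)]) & set(subj[list(te)])

    def test_train_size_near_target(self):
        meta = generate_metadata(CohortDesign(seed=29))  # ~165 samples
        for seed in range(10):
            plan = split_by_subject(meta, 0.7, seed=seed)
            assert abs(len(plan.train_samples) - 0.7 * len(meta)) <= 8

    def test_deterministic_given_seed(self, cohort_meta):
        p1 = split_by_subject(cohort_meta, 0.7, seed=5)
        p2 = split_by_subject(cohort_meta, 0.7, seed=5)
        assert p1.train_samples == p2.train_samples

    def test_single_subject_group_rejected(self):
        meta = pd.DataFrame({
            "sample_id": ["A_HIP", "A_TCx", "C1_HIP", "C2_HIP"],
            "subject_id": ["A", "A", "C1", "C2"],
            "diagnosis": ["AD", "AD", "control", "control"],
        })
        with pytest.raises(ValueError, match="single subject"):
            split_by_subject(meta, 0.7, seed=0)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(train_samples=["s1"], test_samples=["s1"],
                      train_frac=0.7, seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["AD", "control", "AD"])
        assert evaluate(y, y) == (1.0, 1.0, 1.0, 1.0)

    def test_paper_style_confusion_matrix(self):
        """precision 0.81, recall 0.97 ⇒ F1 rounds to 0.88."""
        tp, fp, fn, tn = 7857, 1843, 243, 5000
        pred = np.array(["AD"] * (tp + fp) + ["control"] * (fn + tn))
        true = np.array(["AD"] * tp + ["control"] * fp
                        + ["AD"] * fn + ["control"] * tn)
        acc, prec, rec, f1 = evaluate(pred, true)
        assert prec == pytest.approx(0.81, abs=1e-12)
        assert rec == pytest.approx(0.97, abs=1e-12)
        assert round(f1, 2) == 0.88

    def test_all_negative_predictions(self):
        pred = np.array(["control", "control"])
        true = np.array(["AD", "control"])
        acc, prec, rec, f1 = evaluate(pred, true)
        assert rec == 0.0 and f1 == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(["AD"], ["AD", "control"])


class TestHoeffding:
    def test_known_value(self):
        eps, bound = hoeffding_bound(0.17, 51, delta=0.5)
        assert eps == pytest.approx(np.sqrt(np.log(4.0) / 102.0), abs=1e-12)
        assert bound == pytest.approx(0.17 + eps, abs=1e-15)

    @given(n1=st.integers(1, 500), n2=st.integers(1, 500),
           delta=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_n(self, n1, n2, delta):
        e1, _ = hoeffding_bound(0.1, min(n1, n2), delta)
        e2, _ = hoeffding_bound(0.1, max(n1, n2), delta)
        assert e2 <= e1

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            hoeffding_bound(0.1, 0, 0.5)
        with pytest.raises(ValueError):
            hoeffding_bound(0.1, 10, 1.5)


class TestPanelSearch:
    def test_combination_counts(self, cohort_meta):
        X = _panel_matrix(cohort_meta, seed=1)
        labels = pd.Series(cohort_meta["diagnosis"].to_numpy(),
                           index=cohort_meta["sample_id"].to_numpy())
        plan = split_by_subject(cohort_meta, 0.7, seed=0)
        reports = panel_search(X, labels, "linear_svm", plan)
        by_n = {r.n_genes: r.n_combinations for r in reports}
        assert by_n[2] == 45
        assert sum(by_n.values()) == 1013  # 2^10 − 1 − 10

    def test_separating_gene_always_selected(self, cohort_meta):
        X = _panel_matrix(cohort_meta, seed=2, separating=True)
        labels = pd.Series(cohort_meta["diagnosis"].to_numpy(),
                           index=cohort_meta["sample_id"].to_numpy())
        plan = split_by_subject(cohort_meta, 0.7, seed=0)
        reports = panel_search(X, labels, "linear_svm", plan)
        assert all("G03" in r.best_panel for r in reports)
        assert all(r.test_acc == 1.0 for r in reports)

    def test_selection_blind_to_test_labels(self, cohort_meta):
        """Shuffling test labels changes no panel and no training accuracy."""
        X = _panel_matrix(cohort_meta, seed=3)
        labels = pd.Series(cohort_meta["diagnosis"].to_numpy(),
                           index=cohort_meta["sample_id"].to_numpy())
        plan = split_by_subject(cohort_meta, 0.7, seed=1)
        rng = np.random.default_rng(4)
        shuffled = labels.copy()
        te = plan.test_samples
        shuffled.loc[te] = rng.permutation(shuffled.loc[te].to_numpy())
        r1 = panel_search(X, labels, "quadratic_bayes", plan)
        r2 = panel_search(X, shuffled, "quadratic_bayes", plan)
        assert [r.best_panel for r in r1] == [r.best_panel for r in r2]
        assert [r.train_acc for r in r1] == [r.train_acc for r in r2]

    def test_bound_invariant(self, cohort_meta):
        X = _panel_matrix(cohort_meta, seed=5)
        labels = pd.Series(cohort_meta["diagnosis"].to_numpy(),
                           index=cohort_meta["sample_id"].to_numpy())
        plan = split_by_subject(cohort_meta, 0.7, seed=2)
        for r in panel_search(X, labels, "quadratic_bayes", plan, n_max=4):
            assert r.out_of_sample_bound == pytest.approx(
                (1.0 - r.test_acc) + r.hoeffding_eps, abs=1e-15)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("nearest_centroid")


class TestPanelSearchEstimator:
    def test_estimator_reports_and_predict(self, cohort_meta):
        X = _panel_matrix(cohort_meta, seed=6, separating=True)
        search = PanelSearch(classifiers=("linear_svm", "quadratic_bayes"),
                             n_min=2, n_max=3, random_state=0)
        search.fit(X, cohort_meta)
        frame = search.report_frame()
        assert len(frame) == 2 * 2  # classifiers × panel sizes
        assert search.best_report_.test_acc == 1.0
        pred = search.predict(X.loc[search.split_.test_samples])
        truth = cohort_meta.set_index("sample_id").loc[
            search.split_.test_samples, "diagnosis"].to_numpy()
        assert np.mean(pred == truth) == 1.0

    def test_no_optimism_on_permuted_labels(self, cohort_meta):
        """Label permutation: test accuracy stays near the majority rate."""
        rng = np.random.default_rng(7)
        accs = []
        for seed in range(8):
            meta = cohort_meta.copy()
            perm = rng.permutation(
                meta.groupby("subject_id")["diagnosis"].first().to_numpy())
            subj_map = dict(zip(sorted(meta["subject_id"].unique()), perm))
            meta["diagnosis"] = meta["subject_id"].map(subj_map)
            X = _panel_matrix(meta, seed=seed)
            labels = pd.Series(meta["diagnosis"].to_numpy(),
                               index=meta["sample_id"].to_numpy())
            plan = split_by_subject(meta, 0.7, seed=seed)
            reports = panel_search(X, labels, "linear_svm", plan,
                                   n_min=2, n_max=3)
            accs.extend(r.test_acc for r in reports)
        majority = (cohort_meta["diagnosis"] == "control").mean()
        assert abs(np.mean(accs) - majority) < 0.1
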