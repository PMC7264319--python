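"""Cross-validated grid evaluation, metrics, and the permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from bmradiomics.evaluation import (
    ClassifierParams,
    CVPlan,
    auc,
    confusion_metrics,
    make_folds,
    permutation_p_value,
    permutation_test,
    render_grid,
    run_grid,
    subgroup_grids,
    train_eval_cell,
    youden_threshold,
)

from conftest import make_table


def _informative_table(n=100, f=20, d=2.0, seed=0, patients_per=2):
    r = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = r.standard_normal((n, f))
    X[:, 0] += d * y
    X[:, 1] += 0.7 * d * y
    patients = np.array([f"P{i // patients_per}" for i in range(n)])
    return make_table(X, y, patients=patients)


LIGHT = dict(
    selector_kwargs={"n_trees": 30},
    classifier_params=ClassifierParams(rf_trees=50),
)


class TestFolds:
    def test_210_lesions_gives_189_21(self):
        tab = _informative_table(n=210, f=4)
        folds = make_folds(tab, CVPlan("kfold", k=10, seed=0))
        sizes = {(len(tr), len(te)) for tr, te in folds}
        assert sizes == {(189, 21)}
        # partition: every lesion in exactly one test fold
        test_all = np.concatenate([te for _, te in folds])
        assert sorted(test_all.tolist()) == list(range(210))

    def test_leave_one_out(self):
        tab = _informative_table(n=12, f=3)
        folds = make_folds(tab, CVPlan("loo"))
        assert len(folds) == 12
        assert all(len(te) == 1 for _, te in folds)

    def test_patient_grouping_never_splits_patient(self):
        tab = _informative_table(n=60, f=3, patients_per=3)
        folds = make_folds(tab, CVPlan("kfold", k=5, grouping="patient", seed=1))
        for tr, te in folds:
            assert not (set(tab.patient_ids[tr]) & set(tab.patient_ids[te]))

    def test_k_exceeding_groups_rejected(self):
        tab = _informative_table(n=20, f=3, patients_per=10)  # 2 patients
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(tab, CVPlan("kfold", k=5, grouping="patient"))

    def test_deterministic_given_seed(self):
        tab = _informative_table(n=50, f=3)
        a = make_folds(tab, CVPlan("kfold", k=5, seed=3))
        b = make_folds(tab, CVPlan("kfold", k=5, seed=3))
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 100.0

    def test_three_of_four_concordant(self):
        assert auc([0.2, 0.9, 0.4, 0.3], [0, 1, 0, 1]) == 75.0

    def test_all_ties_is_chance(self):
        assert auc([0.5] * 8, [0, 1] * 4) == 50.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_sklearn_on_random_scores(self):
        r = np.random.default_rng(0)
        for _ in range(20):
            y = r.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(r.normal(size=30), 1)  # ties likely
            assert np.isclose(auc(s, y), 100 * roc_auc_score(y, s))

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["exp", "cube", "affine"]))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed, kind):
        r = np.random.default_rng(seed)
        y = np.array([0, 1] * 10)
        s = r.normal(size=20)
        t = {"exp": np.exp(s), "cube": s**3, "affine": 3 * s + 1}[kind]
        assert np.isclose(auc(s, y), auc(t, y))


class TestConfusionMetrics:
    def test_perfect_scores(self):
        m = confusion_metrics([0, 0, 1, 1], [0, 0, 1, 1], threshold=0.5)
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 100.0

    def test_predict_all_positive(self):
        m = confusion_metrics([1, 1, 1, 1], [0, 1, 0, 1], threshold=0.5)
        assert m["sensitivity"] == 100.0 and m["specificity"] == 0.0

    def test_hand_counts(self):
        # TP=3 FN=1 TN=4 FP=1
        scores = [1, 1, 1, 0] + [0, 0, 0, 0, 1]
        labels = [1, 1, 1, 1] + [0, 0, 0, 0, 0]
        m = confusion_metrics(scores, labels, threshold=0.5)
        assert np.isclose(m["sensitivity"], 75.0)
        assert np.isclose(m["specificity"], 80.0)
        assert np.isclose(m["accuracy"], 700 / 9)

    def test_youden_threshold_separates_perfectly_separable(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        t = youden_threshold(scores, labels)
        m = confusion_metrics(scores, labels, t)
        assert m["sensitivity"] == m["specificity"] == 100.0


class TestPermutationFormula:
    def test_printed_formula(self):
        assert np.isclose(permutation_p_value(0, 500), 1 / 501)
        assert permutation_p_value(500, 500) == 1.0

    def test_bounds(self):
        with pytest.raises(ValueError):
            permutation_p_value(5, 4)
        with pytest.raises(ValueError):
            permutation_p_value(0, 0)


class TestTrainEvalCell:
    def test_strong_signal_high_auc(self):
        tab = _informative_table(n=120, f=20, d=2.0, seed=1)
        cell = train_eval_cell(
            tab, "mrmr", "rf", CVPlan("kfold", k=5, seed=0), k_grid=[2, 5], seed=0, **LIGHT
        )
        assert cell.auc > 85
        assert cell.optimal_k in (2, 5)
        assert 0 <= cell.sensitivity <= 100 and 0 <= cell.specificity <= 100

    def test_shuffled_labels_near_chance(self):
        tab = _informative_table(n=120, f=20, d=2.0, seed=2)
        r = np.random.default_rng(9)
        shuffled = make_table(tab.X, r.permutation(tab.y), patients=tab.patient_ids)
        cell = train_eval_cell(
            shuffled, "mrmr", "rf", CVPlan("kfold", k=5, seed=0), k_grid=[5], seed=0, **LIGHT
        )
        assert 40 <= cell.auc <= 60

    def test_deterministic_rerun(self):
        tab = _informative_table(n=60, f=10, seed=3)
        args = (tab, "relieff", "rf", CVPlan("kfold", k=5, seed=2))
        a = train_eval_cell(*args, k_grid=[3], seed=5, **LIGHT)
        b = train_eval_cell(*args, k_grid=[3], seed=5, **LIGHT)
        assert a.auc == b.auc and a.per_fold_scores == b.per_fold_scores

    def test_unknown_names_rejected(self):
        tab = _informative_table(n=40, f=5)
        with pytest.raises(ValueError, match="selector"):
            train_eval_cell(tab, "pca", "rf", CVPlan("kfold", k=4))
        with pytest.raises(ValueError, match="classifier"):
            train_eval_cell(tab, "mrmr", "mlp", CVPlan("kfold", k=4))

    def test_audit_proves_no_leakage(self):
        tab = _informative_table(n=60, f=10, seed=4)
        cell = train_eval_cell(
            tab, "mrmr", "rf", CVPlan("kfold", k=5, seed=1), k_grid=[3], seed=0, **LIGHT
        )
        seen_test = []
        for entry in cell.audit:
            train, test = set(entry["train_lesions"]), set(entry["test_lesions"])
            assert not train & test
            assert train | test == set(tab.lesion_ids)
            seen_test.extend(entry["test_lesions"])
        assert sorted(seen_test) == sorted(tab.lesion_ids)


class TestPermutationTest:
    def test_null_p_not_small_and_signal_p_small(self):
        plan = CVPlan("kfold", k=4, seed=0)
        kwargs = dict(
            k_grid=[2], seed=1, n_permutations=19,
            selector_kwargs={"n_neighbors": 5},
            classifier_params=ClassifierParams(rf_trees=25),
        )
        signal = _informative_table(n=48, f=6, d=2.5, seed=5)
        res = permutation_test(signal, "relieff", "rf", plan, **kwargs)
        assert res.p_value == permutation_p_value(res.n_higher, res.n_permutations)
        assert res.p_value <= 0.10

        null = _informative_table(n=48, f=6, d=0.0, seed=6)
        res0 = permutation_test(null, "relieff", "rf", plan, **kwargs)
        assert res0.p_value > 0.05

    def test_patient_wise_permutation_keeps_lesions_together(self):
        # patient-wise shuffling requires patient-constant labels to stay
        # patient-constant and the permuted pipeline to run through
        r = np.random.default_rng(7)
        patients = np.repeat([f"P{i}" for i in range(10)], 4)
        y = np.repeat(np.tile([0, 1], 5), 4)  # label constant per patient
        tab = make_table(r.standard_normal((40, 5)), y, patients=patients)
        plan = CVPlan("kfold", k=3, grouping="patient", seed=0)
        res = permutation_test(
            tab, "laplacian", "rf", plan, n_permutations=3, seed=0, k_grid=[2],
            classifier_params=ClassifierParams(rf_trees=15),
        )
        assert res.n_permutations == 3

    def test_super_uniform_under_null(self):
        """Rejection rate at nominal 0.2 stays near/below 0.2 on null cohorts."""
        plan = CVPlan("kfold", k=4, seed=0)
        rejections = 0
        n_sims = 25
        for s in range(n_sims):
            tab = _informative_table(n=32, f=6, d=0.0, seed=200 + s)
            res = permutation_test(
                tab, "laplacian", "rf", plan, n_permutations=19, seed=s,
                k_grid=[2], classifier_params=ClassifierParams(rf_trees=15),
            )
            rejections += res.p_value <= 0.2
        # binomial(25, 0.2): P(X > 10) < 0.01
        assert rejections <= 10


class TestSubgroupsAndGrid:
    def test_subgroups_partition_cohort(self):
        r = np.random.default_rng(0)
        diam = r.uniform(4, 30, size=80)
        tab = make_table(r.standard_normal((80, 6)), np.tile([0, 1], 40), diameters=diam)
        grids = subgroup_grids(
            tab, threshold_mm=10.0, selectors=("laplacian",), classifiers=("rf",),
            k_grid=[2], kfold_k=4, classifier_params=ClassifierParams(rf_trees=15),
        )
        n_small = (diam <= 10).sum()
        n_large = (diam > 10).sum()
        assert n_small + n_large == 80
        assert set(grids) == {"small", "large"}

    def test_all_small_skips_large_grid(self):
        r = np.random.default_rng(1)
        tab = make_table(
            r.standard_normal((40, 4)), np.tile([0, 1], 20), diameters=np.full(40, 5.0)
        )
        with pytest.warns(UserWarning, match="skipped"):
            grids = subgroup_grids(
                tab, selectors=("laplacian",), classifiers=("rf",), k_grid=[2],
                kfold_k=4, classifier_params=ClassifierParams(rf_trees=15),
            )
        assert "large" not in grids

    def test_effect_planted_only_in_small_lesions(self):
        r = np.random.default_rng(2)
        n = 120
        y = np.tile([0, 1], n // 2)
        diam = np.where(np.arange(n) < n // 2, 6.0, 20.0)
        X = r.standard_normal((n, 8))
        small = diam <= 10
        X[small, 0] += 2.5 * y[small]  # signal only in small lesions
        tab = make_table(X, y, diameters=diam)
        grids = subgroup_grids(
            tab, selectors=("relieff",), classifiers=("rf",), k_grid=[2],
            kfold_k=5, classifier_params=ClassifierParams(rf_trees=40),
            selector_kwargs={"n_neighbors": 5},
        )
        small_auc = grids["small"].cells[("relieff", "rf")].auc
        large_auc = grids["large"].cells[("relieff", "rf")].auc
        assert small_auc > large_auc + 10

    def test_render_grid_csv_roundtrip(self, tmp_path):
        tab = _informative_table(n=40, f=6, seed=8)
        rep = run_grid(
            tab, CVPlan("kfold", k=4, seed=0), selectors=("laplacian", "mrmr"),
            classifiers=("rf",), k_grid=[2], seed=0,
            classifier_params=ClassifierParams(rf_trees=15),
        )
        mat = render_grid(rep, tmp_path / "auc.csv", tmp_path / "auc.png")
        import pandas as pd

        back = pd.read_csv(tmp_path / "auc.csv", index_col="classifier")
        assert np.allclose(back.to_numpy(), mat.to_numpy(dtype=float))
        assert (tmp_path / "auc.png").exists()
        assert list(back.columns) == ["mrmr", "laplacian"]


def test_pipeline_auc_monotone_in_effect_size(null_table, weak_table, strong_table):
    """Pooled CV AUC of the RF/RF cell rises with the planted texture
    effect: none -> weak (1.33x correlation ratio) -> strong (2x),
    up to simulation error."""
    light = dict(
        k_grid=[10], seed=11,
        selector_kwargs={"n_trees": 30},
        classifier_params=ClassifierParams(rf_trees=100),
    )
    plan = CVPlan("kfold", k=10, grouping="lesion", seed=17)
    aucs = {
        name: train_eval_cell(tab, "rf", "rf", plan, **light).auc
        for name, tab in (
            ("null", null_table), ("weak", weak_table), ("strong", strong_table)
        )
    }
    slack = 5.0  # AUC points of Monte Carlo slack
    assert aucs["null"] <= aucs["weak"] + slack
    assert aucs["weak"] <= aucs["strong"] + slack
    assert aucs["strong"] > aucs["null"] + 20
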