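from types import SimpleNamespace

import numpy as np
import pytest

from chromstab import (
    ExperimentReport,
    RankedFeature,
    evaluate,
    feature_intersection_across_experiments,
    fit_pipeline_cv,
    make_spec,
    rank_features,
    summary_table,
)



def _stub_model(predictions):
    return SimpleNamespace(
        predict=lambda X: np.asarray(predictions),
        cv_f1_mean=0.7, cv_f1_std=0.05,
        cv_precision_mean=0.7, cv_precision_std=0.05,
        cv_recall_mean=0.7, cv_recall_std=0.05,
        train_f1=1.0, best_params={"clf__C": 1},
    )


def _test_view(y):
    y = np.asarray(y)
    return SimpleNamespace(X=np.zeros((len(y), 2)), y=y)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0] * 6 + [1] * 4)
        rep = evaluate(_stub_model(y), _test_view(y))
        assert rep.test_f1 == 1.0
        assert rep.confusion == (6, 0, 0, 4)
        assert rep.per_class[0]["f1"] == rep.per_class[1]["f1"] == 1.0

    def test_confusion_arithmetic_on_imbalanced_test(self):
        """TN=27 FP=4 FN=4 TP=1 on n=36 gives recall(0)=27/31."""
        y = np.array([0] * 31 + [1] * 5)
        pred = np.concatenate(
            [np.zeros(27), np.ones(4), np.zeros(4), np.ones(1)]
        ).astype(int)
        rep = evaluate(_stub_model(pred), _test_view(y))
        assert rep.confusion == (27, 4, 4, 1)
        assert rep.per_class[0]["recall"] == pytest.approx(27 / 31)
        assert rep.per_class[1]["precision"] == pytest.approx(1 / 5)
        assert rep.per_class[1]["recall"] == pytest.approx(1 / 5)
        assert sum(rep.confusion) == rep.n_test == 36

    def test_no_predicted_positives_warns_not_raises(self):
        y = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="class 1"):
            rep = evaluate(_stub_model(np.zeros(10, int)), _test_view(y))
        assert rep.per_class[1]["precision"] == 0.0
        assert rep.per_class[1]["f1"] == 0.0

    def test_metrics_recomputable_from_confusion(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 40)
        pred = rng.integers(0, 2, 40)
        rep = evaluate(_stub_model(pred), _test_view(y))
        tn, fp, fn, tp = rep.confusion
        prec1 = tp / (tp + fp) if tp + fp else 0.0
        rec1 = tp / (tp + fn) if tp + fn else 0.0
        f1_1 = 2 * prec1 * rec1 / (prec1 + rec1) if prec1 + rec1 else 0.0
        assert rep.per_class[1]["f1"] == pytest.approx(f1_1)
        prec0 = tn / (tn + fn) if tn + fn else 0.0
        rec0 = tn / (tn + fp) if tn + fp else 0.0
        f1_0 = 2 * prec0 * rec0 / (prec0 + rec0) if prec0 + rec0 else 0.0
        w = ((y == 0).mean() * f1_0 + (y == 1).mean() * f1_1)
        assert rep.test_f1 == pytest.approx(w)


def _fitted(fs, clf, cohort, grid):
    spec = make_spec(fs, "none", clf, grid=grid)
    spec.fs_keep_fraction = 0.2
    view = cohort.view(chromosome=1, include_covariates=False)
    return fit_pipeline_cv(view, spec, seed=0), spec


class TestRankFeatures:
    def test_linear_svm_ranked_by_absolute_weight_with_sign(self, two_chrom_cohort):
        fitted, spec = _fitted("anova", "linear_svm", two_chrom_cohort,
                               {"clf__C": [1]})
        ranked = rank_features(fitted, spec)
        w = np.abs(fitted.classifier.coef_.ravel())
        assert [r.value for r in ranked] == sorted(
            [float(x) for x in w], reverse=True
        )
        assert all(r.sign in "+-." for r in ranked)
        assert all(r.source == "svm_weight" for r in ranked)

    def test_svm_sign_follows_weight(self):
        # direct check of the rule on constructed weights (-2, 0.5)
        from chromstab.pipeline_core import FittedPipeline, PipelineSpec

        spec = PipelineSpec("anova", "none", "linear_svm",
                            grid={"clf__C": [1]})
        clf = SimpleNamespace(coef_=np.array([[-2.0, 0.5]]))
        model = FittedPipeline(
            spec=spec, best_params={}, cv_f1_mean=0, cv_f1_std=0,
            cv_precision_mean=0, cv_precision_std=0, cv_recall_mean=0,
            cv_recall_std=0, impute_means=np.zeros(2),
            var_mask=np.ones(2, bool), scaler_stats=(np.zeros(2), np.ones(2)),
            support_mask=np.ones(2, bool), fs_scores=np.zeros(2),
            classifier=clf, feature_names=["f0", "f1"],
            is_snp=np.ones(2, bool), train_f1=0,
        )
        ranked = rank_features(model, spec)
        assert ranked[0].feature == "f0" and ranked[0].sign == "-"
        assert ranked[1].feature == "f1" and ranked[1].sign == "+"

    def test_knn_anova_ranked_by_ascending_pvalue(self, two_chrom_cohort):
        fitted, spec = _fitted("anova", "knn", two_chrom_cohort,
                               {"clf__n_neighbors": [5]})
        ranked = rank_features(fitted, spec)
        pvals = [r.value for r in ranked]
        assert pvals == sorted(pvals)
        assert all(r.source == "fs_pvalue" and r.sign == "." for r in ranked)

    def test_knn_rlr_ranked_by_descending_coefficient(self, two_chrom_cohort):
        fitted, spec = _fitted("rlr_l1", "knn", two_chrom_cohort,
                               {"clf__n_neighbors": [5], "fs__C": [1]})
        ranked = rank_features(fitted, spec)
        vals = [r.value for r in ranked]
        assert vals == sorted(vals, reverse=True)
        assert all(r.source == "fs_coefficient" for r in ranked)

    def test_rf_importances_normalized_before_ranking(self, two_chrom_cohort):
        fitted, spec = _fitted("anova", "rf", two_chrom_cohort,
                               {"clf__n_estimators": [30]})
        ranked = rank_features(fitted, spec)
        assert sum(r.value for r in ranked) == pytest.approx(1.0)
        assert all(r.sign == "." for r in ranked)  # ANOVA carries no sign
        vals = [r.value for r in ranked]
        assert vals == sorted(vals, reverse=True)


def _report(name, fs, clf, snps):
    return ExperimentReport(
        name=name, fs_method=fs, sampling="none", classifier=clf,
        ranked_features=[RankedFeature(s, 1.0, "+", "svm_weight") for s in snps],
    )


class TestFeatureIntersection:
    def test_identical_sets_match_fully(self):
        reports = [
            _report(f"e{i}", "anova", "linear_svm", ["a", "b", "c"])
            for i in range(3)
        ]
        df = feature_intersection_across_experiments(reports)
        assert df.loc[0, "n_match"] == 3
        assert df.loc[0, "n_experiments"] == 3

    def test_partial_overlap(self):
        reports = [
            _report("e1", "anova", "knn", ["a", "b"]),
            _report("e2", "anova", "knn", ["b", "c"]),
        ]
        df = feature_intersection_across_experiments(reports)
        assert df.loc[0, "n_match"] == 1

    def test_groups_are_fs_plus_classifier(self):
        reports = [
            _report("e1", "anova", "knn", ["a"]),
            _report("e2", "anova", "rf", ["a"]),
            _report("e3", "anova", "knn", ["a"]),
        ]
        df = feature_intersection_across_experiments(reports)
        assert len(df) == 1  # only the knn pair forms a group
        assert df.loc[0, "classifier"] == "knn"


class TestSummaryTable:
    def test_sorted_by_cv_f1_descending(self, two_chrom_cohort):
        from chromstab import run_experiment_grid

        splits_ds = two_chrom_cohort
        from chromstab import stratified_three_way_split

        splits = stratified_three_way_split(splits_ds, 0.2, 0.5, seed=1)
        reports = run_experiment_grid(
            splits, fs_methods=["anova"], samplings=["none", "up"],
            classifiers=["linear_svm"], seed=2, S=3, T=0.8, W=1,
            grids={"clf__C": [1]}, include_covariates=False,
        )
        df = summary_table(reports)
        col = df["cv_f1_mean"].to_numpy()
        assert (col[:-1] >= col[1:]).all()
        assert set(df.columns) >= {"test_f1_0", "test_f1_1", "n_features"}
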