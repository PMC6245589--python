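import numpy as np
import pytest
from scipy import stats as sps

from chromstab import (
    filter_and_merge,
    make_spec,
    partial_analysis,
    run_experiment,
    run_experiment_grid,
    stability_scores,
    stratified_three_way_split,
)
from chromstab.stability_framework import (
    NoStableFeaturesError,
    StabilityResult,
    _stratified_subsample,
)

from conftest import REDUCED_GRID


@pytest.fixture(scope="module")
def splits(two_chrom_cohort):
    return stratified_three_way_split(two_chrom_cohort, 0.2, 0.5, seed=3)


@pytest.fixture(scope="module")
def anova_partial(splits):
    spec = make_spec("anova", "none", "linear_svm", grid={"clf__C": [1]})
    view = splits.train.view(chromosome=1, include_covariates=False)
    return partial_analysis(view, spec, seed=5, chromosome=1)


class TestStabilityScores:
    def test_scores_bounded_by_s(self, anova_partial, splits):
        view = splits.stability.view(chromosome=1, include_covariates=False)
        res = stability_scores(anova_partial, view, S=10, T=0.8, seed=1)
        assert res.scores.min() >= 0 and res.scores.max() <= 10
        assert res.scores.shape == (view.n_features,)

    def test_full_subsample_gives_all_or_nothing_scores(self, anova_partial, splits):
        """With T=1 every refit sees the whole stability set, so scores are
        0 or S and the S-scored set equals an independent ANOVA selection."""
        view = splits.stability.view(chromosome=1, include_covariates=False)
        res = stability_scores(anova_partial, view, S=5, T=1.0, seed=2)
        assert set(np.unique(res.scores)) <= {0, 5}
        # independent oracle: impute -> drop zero variance -> one-way F,
        # keep ceil(2% of columns) smallest p-values
        X, y = view.X.copy(), view.y
        col_mean = np.nanmean(X, axis=0)
        ix = np.where(np.isnan(X))
        X[ix] = col_mean[ix[1]]
        keepvar = X.var(axis=0) > 0
        pv = np.full(X.shape[1], np.inf)
        for j in np.flatnonzero(keepvar):
            _, p = sps.f_oneway(X[y == 0, j], X[y == 1, j])
            pv[j] = p
        k = int(np.ceil(0.02 * X.shape[1]))
        expected = np.zeros(X.shape[1], dtype=bool)
        expected[np.argsort(pv, kind="stable")[:k]] = True
        np.testing.assert_array_equal(res.scores == 5, expected)

    def test_scores_match_loop_and_count_oracle(self, splits):
        """30-sample, 20-SNP fixture, S=10: the package's scores equal a
        literal loop-and-count with an independently coded selection step."""
        rng = np.random.default_rng(21)
        take = rng.choice(splits.stability.n_samples, 30, replace=False)
        small = splits.stability.take(np.sort(take))
        cols = np.flatnonzero(small.snp_map["chrom"].to_numpy() == 1)[:20]
        view = small.view(snp_columns=cols, include_covariates=False)

        spec = make_spec("anova", "none", "linear_svm", grid={"clf__C": [1]})
        train_view = splits.train.view(
            snp_columns=np.flatnonzero(
                splits.train.snp_map["chrom"].to_numpy() == 1
            )[:20],
            include_covariates=False,
        )
        partial = partial_analysis(train_view, spec, seed=5, chromosome=1)
        S, T, seed = 10, 0.8, 9
        res = stability_scores(partial, view, S=S, T=T, seed=seed)

        # oracle: same subsample draws, independent selection arithmetic
        oracle_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        oracle = np.zeros(view.n_features, dtype=int)
        k = int(np.ceil(spec.fs_keep_fraction * view.n_features))
        for _ in range(S):
            idx = _stratified_subsample(view.y, T, oracle_rng)
            X = view.X[idx].copy()
            y = view.y[idx]
            mu = np.nanmean(X, axis=0)
            w = np.where(np.isnan(X))
            X[w] = mu[w[1]]
            keepvar = X.var(axis=0) > 0
            pv = np.full(X.shape[1], np.inf)
            for j in np.flatnonzero(keepvar):
                _, p = sps.f_oneway(X[y == 0, j], X[y == 1, j])
                pv[j] = 1.0 if np.isnan(p) else p
            sel = np.argsort(pv, kind="stable")[:k]
            oracle[sel] += 1
        np.testing.assert_array_equal(res.scores, oracle)

    def test_deterministic_under_seed(self, anova_partial, splits):
        view = splits.stability.view(chromosome=1, include_covariates=False)
        a = stability_scores(anova_partial, view, S=8, T=0.8, seed=4)
        b = stability_scores(anova_partial, view, S=8, T=0.8, seed=4)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_scores_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, S\\]"):
            StabilityResult(
                chromosome=1, feature_names=["a"], is_snp=np.array([True]),
                scores=np.array([11]), S=10, T=0.8, best_params={},
                cv_f1_mean=0.5, cv_f1_std=0.1,
            )


def _make_results(splits, score_by_chrom):
    """StabilityResults with prescribed scores for each chromosome."""
    out = []
    for chrom, scores in score_by_chrom.items():
        view = splits.stability.view(chromosome=chrom, include_covariates=False)
        out.append(
            StabilityResult(
                chromosome=chrom,
                feature_names=view.feature_names,
                is_snp=view.is_snp,
                scores=np.asarray(scores),
                S=100, T=0.8, best_params={}, cv_f1_mean=0.5, cv_f1_std=0.1,
            )
        )
    return out


class TestFilterAndMerge:
    def test_w_zero_keeps_union_of_all_features(self, splits):
        n = 25
        results = _make_results(
            splits, {1: np.zeros(n, int), 2: np.arange(n) % 101}
        )
        merged = filter_and_merge(results, 0, splits, include_covariates=False)
        assert len(merged.feature_names) == 2 * n

    def test_w_equal_s_keeps_only_always_selected(self, splits):
        n = 25
        s1 = np.zeros(n, int)
        s1[3] = 100
        results = _make_results(splits, {1: s1, 2: np.full(n, 99)})
        merged = filter_and_merge(results, 100, splits, include_covariates=False)
        assert merged.feature_names == [
            splits.train.view(chromosome=1).feature_names[3]
        ]

    def test_threshold_monotonicity(self, splits):
        rng = np.random.default_rng(8)
        n = 25
        results = _make_results(
            splits,
            {1: rng.integers(0, 101, n), 2: rng.integers(0, 101, n)},
        )
        sets = {}
        for W in (0, 50, 100):
            try:
                m = filter_and_merge(results, W, splits, include_covariates=False)
                sets[W] = set(m.feature_names)
            except NoStableFeaturesError:
                sets[W] = set()
        assert sets[100] <= sets[50] <= sets[0]

    def test_empty_union_raises_named_error(self, splits):
        n = 25
        results = _make_results(splits, {1: np.zeros(n, int), 2: np.zeros(n, int)})
        with pytest.raises(NoStableFeaturesError, match="expX"):
            filter_and_merge(
                results, 100, splits, include_covariates=False, experiment="expX"
            )

    def test_mismatched_s_rejected(self, splits):
        results = _make_results(splits, {1: np.zeros(25, int)})
        results.append(
            StabilityResult(
                chromosome=2, feature_names=["z"], is_snp=np.array([True]),
                scores=np.array([1]), S=10, T=0.8, best_params={},
                cv_f1_mean=0.5, cv_f1_std=0.1,
            )
        )
        with pytest.raises(ValueError, match="share S"):
            filter_and_merge(results, 5, splits)

    def test_sample_sets_unchanged_by_merge(self, splits):
        results = _make_results(
            splits, {1: np.full(25, 100), 2: np.zeros(25, int)}
        )
        merged = filter_and_merge(results, 100, splits, include_covariates=False)
        assert merged.train_view.sample_ids == splits.train.sample_ids
        assert merged.test_view.sample_ids == splits.test.sample_ids


class TestExperimentChain:
    def test_one_stability_result_per_chromosome(self, splits):
        rep = run_experiment(
            splits, "anova", "none", "linear_svm",
            seed=1, S=5, T=0.8, W=1, grids={"clf__C": [1]},
            include_covariates=False,
        )
        assert not rep.failed
        assert sorted(r.chromosome for r in rep.stability_results) == [1, 2]

    def test_same_seed_identical_experiment(self, splits):
        kw = dict(seed=2, S=5, T=0.8, W=2, grids={"clf__C": [1]},
                  include_covariates=False)
        a = run_experiment(splits, "anova", "none", "linear_svm", **kw)
        b = run_experiment(splits, "anova", "none", "linear_svm", **kw)
        assert a.to_json() == b.to_json()
        for ra, rb in zip(a.stability_results, b.stability_results):
            np.testing.assert_array_equal(ra.scores, rb.scores)

    def test_final_stages_fit_on_merged_train_only(self, splits):
        """Leakage contract: the final model's imputation means are the
        merged training-view column means, never test statistics."""
        from chromstab import final_analysis

        results = _make_results(
            splits, {1: np.full(25, 100), 2: np.zeros(25, int)}
        )
        merged = filter_and_merge(results, 100, splits, include_covariates=False)
        spec = make_spec("anova", "none", "linear_svm", mode="final",
                         grid={"clf__C": [1]})
        fitted, report = final_analysis(merged, spec, seed=4)
        np.testing.assert_allclose(
            fitted.impute_means, np.nanmean(merged.train_view.X, axis=0)
        )
        test_means = np.nanmean(merged.test_view.X, axis=0)
        assert not np.allclose(fitted.impute_means, test_means)
        assert report.n_test == splits.test.n_samples

    def test_grid_cross_product_cardinality(self, splits):
        reports = run_experiment_grid(
            splits,
            fs_methods=["anova", "rlr_l1"],
            samplings=["none", "up"],
            classifiers=["linear_svm", "rf", "knn"],
            seed=3, S=3, T=0.8, W=1, grids=REDUCED_GRID,
            include_covariates=False,
        )
        assert len(reports) == 12
        assert len({r.name for r in reports}) == 12

    def test_single_menu_single_experiment(self, splits):
        reports = run_experiment_grid(
            splits, fs_methods=["anova"], samplings=["none"],
            classifiers=["knn"], seed=3, S=3, T=0.8, W=1,
            grids=REDUCED_GRID, include_covariates=False,
        )
        assert len(reports) == 1

    def test_failed_experiment_recorded_not_raised(self, splits):
        reports = run_experiment_grid(
            splits, fs_methods=["anova"], samplings=["none"],
            classifiers=["linear_svm", "knn"], seed=3, S=3, T=0.8, W=1,
            grids={"clf__C": [], "clf__n_neighbors": [5]},
            include_covariates=False,
        )
        by_clf = {r.classifier: r for r in reports}
        assert by_clf["linear_svm"].failed  # empty grid for the SVM
        assert "grid" in by_clf["linear_svm"].error
        assert not by_clf["knn"].failed
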