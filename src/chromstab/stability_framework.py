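"""Chromosome-partitioned stability selection and the merged final model.

The framework tunes one pipeline per chromosome on the training set
("partial analysis"), then measures how stably each feature is selected:
S stratified subsamples of T percent of an independent stability set are
drawn without replacement, the tuned pipeline's preprocessing and
feature-selection stages are refit on each, and a feature's stability
score counts the refits whose support contains it (range [0, S]).
Features scoring at least the threshold W on their chromosome are merged
across the genome into filtered train/test views, on which the same
pipeline configuration is re-tuned ("final analysis") and evaluated on
the untouched test set.

Keeping the stability set disjoint from both the training and test sets
limits the selection bias the merge step would otherwise inject into
final-model evaluation; the residual bias (no outer CV around the merge)
is a documented property of the design, not corrected here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data_model import DatasetView, GenotypeDataset, SplitBundle, stratified_allocation
from .pipeline_core import (
    CLASSIFIERS,
    FS_METHODS,
    SAMPLING_METHODS,
    FittedPipeline,
    PipelineError,
    fit_pipeline_cv,
    fit_pipeline_stages,
    make_spec,
)
from .reporting import EvaluationReport, ExperimentReport, evaluate, rank_features

logger = logging.getLogger(__name__)


class NoStableFeaturesError(RuntimeError):
    """No feature reached the stability threshold W in any chromosome."""


@dataclass
class StabilityResult:
    """Per-feature stability scores for one chromosome's partial model."""

    chromosome: int
    feature_names: list
    is_snp: np.ndarray
    scores: np.ndarray  # integer, in [0, S]
    S: int
    T: float
    best_params: dict
    cv_f1_mean: float
    cv_f1_std: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=int)
        if ((self.scores < 0) | (self.scores > self.S)).any():
            raise ValueError("stability scores must lie in [0, S]")

    def to_frame(self, snp_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "chrom": self.chromosome,
                "is_snp": self.is_snp.astype(int),
                "score": self.scores,
            }
        )
        if snp_meta is not None:
            pos = {r.snp_id: r.pos for r in snp_meta.itertuples()}
            df["pos"] = [pos.get(f, -1) for f in df["feature"]]
        return df


@dataclass
class MergedDataset:
    """Cross-chromosome train/test views of stability-surviving features."""

    train_view: DatasetView
    test_view: DatasetView
    W: int
    selected_by_chromosome: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list:
        return self.train_view.feature_names


def _stratified_subsample(y, frac, rng, max_retries=10):
    """Indices of a stratified draw of ceil(frac*n) samples w/o replacement."""
    classes, counts = np.unique(y, return_counts=True)
    total, per_class = stratified_allocation(counts, frac)
    total = int(np.ceil(frac * len(y)))
    # re-balance largest-remainder allocation to the ceil total
    while per_class.sum() < total:
        per_class[int(np.argmax(counts - per_class))] += 1
    for _ in range(max_retries):
        idx = []
        for c, k in zip(classes, per_class):
            pool = np.flatnonzero(y == c)
            if k < 1 or k > len(pool):
                break
            idx.extend(rng.choice(pool, size=k, replace=False))
        else:
            return np.sort(np.asarray(idx, dtype=int))
    raise PipelineError("could not draw a stability subsample containing every class")


def partial_analysis(
    chromosome_view: DatasetView, spec, seed: int, chromosome: int
) -> FittedPipeline:
    """Tune the pipeline on one chromosome's training view by k-fold CV."""
    fitted = fit_pipeline_cv(chromosome_view, spec, seed=seed)
    fitted.chromosome = chromosome
    if not fitted.support_mask.any():
        warnings.warn(
            f"chromosome {chromosome}: empty feature support after selection",
            stacklevel=2,
        )
    return fitted


def stability_scores(
    partial: FittedPipeline,
    stability_view: DatasetView,
    S: int = 100,
    T: float = 0.8,
    seed: int = 0,
) -> StabilityResult:
    """Count, over S subsample refits, how often each feature is selected.

    Each refit draws ceil(T*n) stability samples without replacement
    (stratified), re-runs imputation, variance filtering, standardization
    and feature selection with the partial model's frozen best
    hyper-parameters, and increments the score of every feature in the
    refit support.  Features a refit's variance filter drops count as not
    selected.
    """
    y = stability_view.y
    if y is None:
        raise PipelineError("stability scoring requires labels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    scores = np.zeros(stability_view.n_features, dtype=int)
    for s in range(S):
        idx = _stratified_subsample(y, T, rng)
        sub = stability_view.take_samples(idx)
        art = fit_pipeline_stages(
            sub.X,
            sub.y,
            partial.spec,
            partial.best_params,
            seed=seed + s,
            feature_names=stability_view.feature_names,
            fit_classifier=False,
        )
        scores += art["support_mask"].astype(int)
    return StabilityResult(
        chromosome=partial.chromosome if partial.chromosome is not None else -1,
        feature_names=list(stability_view.feature_names),
        is_snp=stability_view.is_snp.copy(),
        scores=scores,
        S=S,
        T=T,
        best_params=dict(partial.best_params),
        cv_f1_mean=partial.cv_f1_mean,
        cv_f1_std=partial.cv_f1_std,
    )


def filter_and_merge(
    results: list[StabilityResult],
    W: int,
    splits: SplitBundle,
    include_covariates: bool = True,
    experiment: str = "",
) -> MergedDataset:
    """Merge, across chromosomes, every feature with stability score >= W.

    Feature order is chromosome order then column order; covariate
    columns contributed by several chromosome views are deduplicated.
    """
    S_values = {r.S for r in results}
    if len(S_values) != 1:
        raise ValueError("all stability results must share S")
    if W > S_values.pop():
        raise ValueError("W cannot exceed S")

    selected = {}
    snp_ids = []
    any_covariate_selected = False
    for res in sorted(results, key=lambda r: r.chromosome):
        keep = [
            (name, bool(is_snp))
            for name, is_snp, sc in zip(res.feature_names, res.is_snp, res.scores)
            if sc >= W
        ]
        chrom_snps = [n for n, is_snp in keep if is_snp]
        snp_ids.extend(chrom_snps)
        any_covariate_selected |= any(not is_snp for _, is_snp in keep)
        selected[res.chromosome] = chrom_snps
    if not snp_ids and not (include_covariates and any_covariate_selected):
        raise NoStableFeaturesError(
            f"experiment {experiment or '<unnamed>'}: no feature reached "
            f"stability threshold W={W} on any chromosome"
        )

    def _merged_view(ds: GenotypeDataset) -> DatasetView:
        id_to_col = {sid: i for i, sid in enumerate(ds.snp_map["snp_id"])}
        cols = np.asarray([id_to_col[s] for s in snp_ids], dtype=int)
        return ds.view(
            snp_columns=cols,
            include_covariates=include_covariates and any_covariate_selected,
        )

    return MergedDataset(
        train_view=_merged_view(splits.train),
        test_view=_merged_view(splits.test),
        W=W,
        selected_by_chromosome=selected,
    )


def final_analysis(
    merged: MergedDataset, spec, seed: int
) -> tuple[FittedPipeline, EvaluationReport]:
    """Re-tune the pipeline on the merged training view and evaluate on the
    merged test view (never resampled, original class distribution)."""
    fitted = fit_pipeline_cv(merged.train_view, spec, seed=seed)
    report = evaluate(fitted, merged.test_view)
    return fitted, report


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------


def _experiment_seed(master_seed: int, exp_index: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([master_seed, exp_index, salt])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    splits: SplitBundle,
    fs_method: str,
    sampling: str,
    classifier: str,
    seed: int,
    S: int = 100,
    T: float = 0.8,
    W: int = 100,
    grids: dict | None = None,
    fs_fractions: dict | None = None,
    include_covariates: bool = True,
    n_jobs: int = 1,
    name: str | None = None,
) -> ExperimentReport:
    """Run the full partial -> stability -> merge -> final chain for one
    pipeline configuration."""
    name = name or f"{fs_method}+{sampling}+{classifier}"
    spec_partial = make_spec(
        fs_method, sampling, classifier, mode="partial",
        grid=grids, fs_fractions=fs_fractions,
    )
    spec_final = make_spec(
        fs_method, sampling, classifier, mode="final",
        grid=grids, fs_fractions=fs_fractions,
    )
    chroms = splits.train.chromosomes()

    def _one_chromosome(ci, chrom):
        cseed = _experiment_seed(seed, ci, salt=1)
        train_view = splits.train.view(
            chromosome=chrom, include_covariates=include_covariates
        )
        partial = partial_analysis(train_view, spec_partial, seed=cseed, chromosome=chrom)
        stab_view = splits.stability.view(
            chromosome=chrom, include_covariates=include_covariates
        )
        result = stability_scores(partial, stab_view, S=S, T=T, seed=cseed)
        logger.info(
            "experiment %s chr%d: cv_f1=%.3f, %d/%d features at score>=%d",
            name, chrom, partial.cv_f1_mean,
            int((result.scores >= W).sum()), result.scores.size, W,
        )
        return result

    stability_results = Parallel(n_jobs=n_jobs)(
        delayed(_one_chromosome)(ci, chrom) for ci, chrom in enumerate(chroms)
    )
    merged = filter_and_merge(
        stability_results, W, splits,
        include_covariates=include_covariates, experiment=name,
    )
    final, evaluation = final_analysis(merged, spec_final, seed=_experiment_seed(seed, 0, salt=2))
    ranked = rank_features(final, spec_final)
    return ExperimentReport(
        name=name,
        fs_method=fs_method,
        sampling=sampling,
        classifier=classifier,
        evaluation=evaluation,
        ranked_features=ranked,
        stability_results=stability_results,
        merged_features=list(merged.feature_names),
        selected_by_chromosome=merged.selected_by_chromosome,
        seed=seed,
    )


def run_experiment_grid(
    splits: SplitBundle,
    fs_methods=FS_METHODS,
    samplings=SAMPLING_METHODS,
    classifiers=CLASSIFIERS,
    seed: int = 0,
    S: int = 100,
    T: float = 0.8,
    W: int = 100,
    grids: dict | None = None,
    fs_fractions: dict | None = None,
    include_covariates: bool = True,
    n_jobs: int = 1,
) -> list[ExperimentReport]:
    """Run every (FS, sampling, classifier) combination; the full menus give
    the 3 x 4 x 3 = 36-experiment grid.  A failing experiment is recorded
    as failed and the grid continues."""
    reports = []
    exp_index = 0
    for fs in fs_methods:
        for sampling in samplings:
            for clf in classifiers:
                exp_name = f"{fs}+{sampling}+{clf}"
                exp_seed = _experiment_seed(seed, exp_index, salt=0)
                try:
                    rep = run_experiment(
                        splits, fs, sampling, clf,
                        seed=exp_seed, S=S, T=T, W=W, grids=grids,
                        fs_fractions=fs_fractions,
                        include_covariates=include_covariates, n_jobs=n_jobs,
                        name=exp_name,
                    )
                except Exception as exc:  # noqa: BLE001 - grid must survive
                    logger.warning("experiment %s failed: %s", exp_name, exc)
                    rep = ExperimentReport(
                        name=exp_name, fs_method=fs, sampling=sampling,
                        classifier=clf, failed=True, error=str(exc), seed=exp_seed,
                    )
                reports.append(rep)
                exp_index += 1
    return reports
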