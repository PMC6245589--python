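"""The six-stage classification pipeline with leakage-safe 5-fold CV.

Stages, in order: mean imputation -> zero-variance filter ->
standardization -> feature selection (ANOVA filter, recursive feature
elimination over L1 logistic regression, or L1-regularized logistic
regression) -> class-imbalance resampling (none / down / up / SMOTE) ->
classifier (linear SVM, random forest, or k-nearest neighbours).

Every stage is fit on training folds only; validation folds are
transformed with the training-fold statistics and are never resampled,
so cross-validation scores estimate performance on the original class
distribution.  Grid search maximizes the class-support-weighted F1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import LinearSVC

from .data_model import DatasetView

FS_METHODS = ("anova", "rfe_lr", "rlr_l1")
SAMPLING_METHODS = ("none", "down", "up", "smote")
CLASSIFIERS = ("linear_svm", "rf", "knn")

#: hyper-parameter grids explored by 5-fold CV grid search
DEFAULT_GRIDS = {
    "linear_svm": {"clf__C": [0.001, 0.01, 0.1, 1, 10, 100, 1000]},
    "rf": {
        "clf__n_estimators": [30, 47, 75, 119, 189, 299, 475, 753, 1194, 1892, 2999]
    },
    "knn": {"clf__n_neighbors": [5, 20, 35, 50]},
    "rlr_l1": {"fs__C": [100, 500, 1000, 1500, 5000, 10000]},
}

#: fraction of features kept by the FS stage in the per-chromosome
#: (partial) and merged (final) analyses, and the RFE elimination step
FS_FRACTIONS = {
    "partial": {"keep": 0.02, "step": 0.04},
    "final": {"keep": 0.10, "step": 0.10},
}

RLR_THRESHOLD = 1e-10


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineSpec:
    """One (feature selection, sampling, classifier) pipeline configuration."""

    fs_method: str
    sampling: str
    classifier: str
    fs_keep_fraction: float = 0.02
    rfe_step_fraction: float = 0.04
    rlr_threshold: float = RLR_THRESHOLD
    grid: dict = field(default_factory=dict)
    k: int = 5

    def __post_init__(self):
        if self.fs_method not in FS_METHODS:
            raise ValueError(f"unknown feature selection method {self.fs_method!r}")
        if self.sampling not in SAMPLING_METHODS:
            raise ValueError(f"unknown sampling method {self.sampling!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not 0.0 < self.fs_keep_fraction <= 1.0:
            raise ValueError("fs_keep_fraction must lie in (0, 1]")
        valid_prefixes = {"fs__", "clf__"}
        for key in self.grid:
            if not any(key.startswith(p) for p in valid_prefixes):
                raise ValueError(f"grid key {key!r} must start with fs__ or clf__")
        if not self.grid:
            self.grid = default_grid(self.fs_method, self.classifier)

    def grid_points(self):
        """All hyper-parameter combinations in declared order."""
        keys = list(self.grid)
        if not keys:
            yield {}
            return
        for values in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, values))


def default_grid(fs_method: str, classifier: str) -> dict:
    grid = dict(DEFAULT_GRIDS.get(classifier, {}))
    if fs_method == "rlr_l1":
        grid.update(DEFAULT_GRIDS["rlr_l1"])
    return grid


def make_spec(
    fs_method: str,
    sampling: str,
    classifier: str,
    mode: str = "partial",
    grid: dict | None = None,
    fs_fractions: dict | None = None,
) -> PipelineSpec:
    """Build a spec with the standard keep/step fractions for the given
    analysis mode ('partial' per chromosome, 'final' on merged data).

    A provided ``grid`` may carry keys for several classifiers (one shared
    override across an experiment grid); only the keys relevant to this
    configuration are kept, falling back to the built-in menus.
    ``fs_fractions`` optionally overrides the mode's keep/step fractions,
    e.g. ``{"final": {"keep": 1.0}}`` to keep every merged feature when
    the merged set is already small."""
    fr = dict(FS_FRACTIONS[mode])
    if fs_fractions and mode in fs_fractions:
        fr.update(fs_fractions[mode])
    if grid is None:
        g = default_grid(fs_method, classifier)
    else:
        allowed = set(default_grid(fs_method, classifier))
        g = {k: v for k, v in grid.items() if k in allowed}
        g = g or default_grid(fs_method, classifier)
    return PipelineSpec(
        fs_method=fs_method,
        sampling=sampling,
        classifier=classifier,
        fs_keep_fraction=fr["keep"],
        rfe_step_fraction=fr["step"],
        grid=g,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def impute_mean(X, fitted_means=None, feature_names=None):
    """Replace missing entries with per-column means.

    At fit time (``fitted_means is None``) means are computed on ``X``;
    at transform time the fitted means are reused so no test-fold
    statistic leaks into the model.  Returns ``(X_imputed, means)``.
    """
    X = np.asarray(X, dtype=float)
    if fitted_means is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fitted_means = np.nanmean(X, axis=0)
        bad = np.flatnonzero(np.isnan(fitted_means))
        if bad.size:
            name = feature_names[bad[0]] if feature_names else f"column {bad[0]}"
            raise PipelineError(f"all values missing for feature {name}")
    out = X.copy()
    miss = np.isnan(out)
    if miss.any():
        out[miss] = np.take(fitted_means, np.nonzero(miss)[1])
    return out, fitted_means


def variance_filter(X):
    """Boolean mask keeping columns with non-zero variance on the fit data."""
    var = np.var(np.asarray(X, dtype=float), axis=0)
    mask = var > 0.0
    if not mask.any():
        warnings.warn("all features have zero variance", stacklevel=2)
    return mask


def standardize(X, fitted_stats=None):
    """Center to zero mean and scale to unit (population) variance.

    Returns ``(X_standardized, (means, scales))``; transform reuses the
    fit statistics.  Raises if a column has zero variance at fit time.
    """
    X = np.asarray(X, dtype=float)
    if fitted_stats is None:
        means = X.mean(axis=0)
        scales = X.std(axis=0)  # population (ddof=0) scaling
        if (scales == 0.0).any():
            raise PipelineError(
                "zero-variance column at standardization fit; "
                "apply variance_filter first"
            )
        fitted_stats = (means, scales)
    means, scales = fitted_stats
    return (X - means) / scales, fitted_stats


def _n_keep(fraction: float, n_features: int) -> int:
    return max(1, min(n_features, math.ceil(fraction * n_features)))


def select_anova(X, y, percentile: float):
    """Keep the ceil(percentile * n) features with smallest one-way
    F-test p-values; ties broken by column order.

    Returns ``(mask, scores)`` where scores are the p-values (all
    features)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise PipelineError("ANOVA selection requires both classes present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _F, pvals = f_classif(X, y)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    k = _n_keep(percentile, X.shape[1])
    order = np.argsort(pvals, kind="stable")  # stable sort = column-order ties
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[order[:k]] = True
    return mask, pvals


def _fit_l1_logreg(X, y, C, seed=0):
    for max_iter in (1000, 10000):
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=max_iter,
            random_state=seed, tol=1e-6,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return model
    raise PipelineError("L1 logistic regression failed to converge")


def select_rfe_lr(X, y, n_keep_fraction: float, step_fraction: float, seed=0):
    """Recursive feature elimination wrapping an L1 logistic regression
    (C=1): each round drops the step-fraction of current features with
    smallest |coefficient| until the keep-fraction remains.

    Returns ``(mask, coefs)`` with the wrapped model's coefficients for
    the surviving features (zeros elsewhere)."""
    n_features = X.shape[1]
    if n_features < 1:
        raise PipelineError("RFE requires at least one feature")
    n_keep = _n_keep(n_keep_fraction, n_features)
    active = np.arange(n_features)
    coefs = np.zeros(n_features)
    while True:
        model = _fit_l1_logreg(X[:, active], y, C=1.0, seed=seed)
        w = model.coef_.ravel()
        if len(active) <= n_keep:
            coefs[active] = w
            break
        step = max(1, int(step_fraction * len(active)))
        step = min(step, len(active) - n_keep)
        drop = np.argsort(np.abs(w), kind="stable")[:step]
        active = np.delete(active, drop)
    mask = np.zeros(n_features, dtype=bool)
    mask[active] = True
    return mask, coefs


def select_rlr_l1(X, y, C: float, threshold: float = RLR_THRESHOLD, seed=0):
    """Embedded selection: fit an L1 logistic regression and keep features
    with |coefficient| >= threshold.  Returns ``(mask, coefs)``."""
    if C <= 0:
        raise ValueError("C must be positive")
    model = _fit_l1_logreg(X, y, C=C, seed=seed)
    coefs = model.coef_.ravel()
    mask = np.abs(coefs) >= threshold
    return mask, coefs


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample(X, y, method: str, seed: int = 0):
    """Rebalance a training set.  'none' is the identity; 'down' subsamples
    the majority class without replacement to the minority size; 'up'
    resamples the minority with replacement to the majority size; 'smote'
    augments the minority to the majority size with synthetic points on
    segments between a minority sample and one of its k nearest minority
    neighbours (k = 5, reduced when the minority is small)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise PipelineError("resampling requires both classes")
    if method == "none":
        return X, y
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    if method == "down":
        keep = rng.choice(maj_idx, size=len(min_idx), replace=False)
        idx = np.sort(np.concatenate([keep, min_idx]))
        return X[idx], y[idx]
    if method == "up":
        extra = rng.choice(min_idx, size=len(maj_idx) - len(min_idx), replace=True)
        idx = np.concatenate([np.arange(len(y)), extra])
        return X[idx], y[idx]
    if method == "smote":
        n_new = len(maj_idx) - len(min_idx)
        if n_new == 0:
            return X, y
        if len(min_idx) < 2:
            raise PipelineError("SMOTE requires at least 2 minority samples")
        k = min(5, len(min_idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[min_idx])
        neigh = nn.kneighbors(X[min_idx], return_distance=False)[:, 1:]
        base = rng.integers(0, len(min_idx), size=n_new)
        pick = rng.integers(0, k, size=n_new)
        gaps = rng.random(n_new)
        parents = X[min_idx][base]
        partners = X[min_idx][neigh[base, pick]]
        synth = parents + gaps[:, None] * (partners - parents)
        Xr = np.vstack([X, synth])
        yr = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return Xr, yr
    raise ValueError(f"unknown sampling method {method!r}")


# ---------------------------------------------------------------------------
# fitted pipeline
# ---------------------------------------------------------------------------


@dataclass
class FittedPipeline:
    """All fit statistics of one tuned pipeline, for exact re-scoring."""

    spec: PipelineSpec
    best_params: dict
    cv_f1_mean: float
    cv_f1_std: float
    cv_precision_mean: float
    cv_precision_std: float
    cv_recall_mean: float
    cv_recall_std: float
    impute_means: np.ndarray
    var_mask: np.ndarray
    scaler_stats: tuple
    support_mask: np.ndarray  # in original column space
    fs_scores: np.ndarray  # p-values (anova) or LR coefficients, original space
    classifier: object
    feature_names: list
    is_snp: np.ndarray
    train_f1: float
    chromosome: int | None = None
    seed: int = 0

    @property
    def selected_features(self) -> list:
        return [n for n, m in zip(self.feature_names, self.support_mask) if m]

    def transform(self, X) -> np.ndarray:
        if self.scaler_stats is None:
            raise PipelineError("pipeline was fit on zero-variance data")
        Xi, _ = impute_mean(X, self.impute_means)
        Xv = Xi[:, self.var_mask]
        Xs, _ = standardize(Xv, self.scaler_stats)
        inner = self.support_mask[self.var_mask]
        return Xs[:, inner]

    def predict(self, X) -> np.ndarray:
        if self.classifier is None:
            raise PipelineError("pipeline has an empty feature support")
        return self.classifier.predict(self.transform(X))


def _make_classifier(name: str, params: dict, seed: int):
    if name == "linear_svm":
        return LinearSVC(C=params.get("clf__C", 1.0), random_state=seed, max_iter=20000)
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=params.get("clf__n_estimators", 100),
            random_state=seed,
            n_jobs=1,
        )
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("clf__n_neighbors", 5))
    raise ValueError(name)


def _fit_fs(Xs, y, spec: PipelineSpec, params: dict, seed: int):
    """Run the FS stage on standardized data; returns (mask, scores)."""
    if spec.fs_method == "anova":
        return select_anova(Xs, y, spec.fs_keep_fraction)
    if spec.fs_method == "rfe_lr":
        return select_rfe_lr(
            Xs, y, spec.fs_keep_fraction, spec.rfe_step_fraction, seed=seed
        )
    if spec.fs_method == "rlr_l1":
        C = params.get("fs__C", 1.0)
        return select_rlr_l1(Xs, y, C=C, threshold=spec.rlr_threshold, seed=seed)
    raise ValueError(spec.fs_method)


def fit_pipeline_stages(X, y, spec: PipelineSpec, params: dict, seed: int,
                        feature_names=None, fit_classifier: bool = True):
    """Fit imputation, variance filter, standardization, FS and (optionally)
    the resampled classifier on one training matrix.

    Returns a dict of fit artefacts; ``support_mask`` and ``fs_scores``
    live in the original column space (variance-dropped columns score 0
    and are never selected)."""
    n_features = X.shape[1]
    Xi, means = impute_mean(X, feature_names=feature_names)
    var_mask = variance_filter(Xi)
    support = np.zeros(n_features, dtype=bool)
    scores = np.zeros(n_features)
    art = {
        "impute_means": means,
        "var_mask": var_mask,
        "scaler_stats": None,
        "support_mask": support,
        "fs_scores": scores,
        "classifier": None,
    }
    if not var_mask.any():
        return art
    Xs, stats = standardize(Xi[:, var_mask])
    art["scaler_stats"] = stats
    fs_mask, fs_scores = _fit_fs(Xs, y, spec, params, seed)
    support[np.flatnonzero(var_mask)[fs_mask]] = True
    if spec.fs_method == "anova":
        scores[:] = 1.0  # p-value scale: dropped columns at the null end
    scores[np.flatnonzero(var_mask)] = fs_scores
    art["support_mask"] = support
    art["fs_scores"] = scores
    if fit_classifier and support.any():
        Xf = Xs[:, fs_mask]
        Xr, yr = resample(Xf, y, spec.sampling, seed=seed)
        clf = _make_classifier(spec.classifier, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xr, yr)
        art["classifier"] = clf
    return art


def weighted_prf(y_true, y_pred):
    """(precision, recall, f1) weighted by class support."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
    return float(p), float(r), float(f)


def fit_pipeline_cv(view: DatasetView, spec: PipelineSpec, seed: int = 0) -> FittedPipeline:
    """Grid-search the spec's hyper-parameters by stratified k-fold CV and
    refit the winning configuration on the full training view.

    Per fold, every stage (imputation, variance filter, standardization,
    feature selection, resampling, classifier) is fit on the training
    folds only; resampling never touches the validation fold.  The best
    setting maximizes mean weighted F1, ties broken by grid order.
    """
    X, y = view.X, view.y
    if y is None:
        raise PipelineError("fit requires labels")
    grid_points = list(spec.grid_points())
    if not grid_points:
        raise PipelineError("empty hyper-parameter grid")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise PipelineError("training view must contain both classes")
    if counts.min() < spec.k:
        raise PipelineError(
            f"minority class ({counts.min()}) smaller than k={spec.k}: "
            "a stratified fold would lose the class"
        )
    skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best = None
    for gi, params in enumerate(grid_points):
        f1s, ps, rs = [], [], []
        for fi, (tr, va) in enumerate(folds):
            art = fit_pipeline_stages(
                X[tr], y[tr], spec, params, seed=seed + fi,
                feature_names=view.feature_names,
            )
            if art["classifier"] is None:
                yhat = np.full(len(va), classes[np.argmax(counts)])
            else:
                fp = _artefacts_to_pipeline(art, spec, params, view, seed)
                yhat = fp.predict(X[va])
            p, r, f = weighted_prf(y[va], yhat)
            f1s.append(f)
            ps.append(p)
            rs.append(r)
        mean_f1 = float(np.mean(f1s))
        if best is None or mean_f1 > best["mean_f1"]:
            best = {
                "params": params, "order": gi, "mean_f1": mean_f1,
                "f1s": f1s, "ps": ps, "rs": rs,
            }

    params = best["params"]
    art = fit_pipeline_stages(
        X, y, spec, params, seed=seed, feature_names=view.feature_names
    )
    fitted = _artefacts_to_pipeline(art, spec, params, view, seed)
    fitted.cv_f1_mean = best["mean_f1"]
    fitted.cv_f1_std = float(np.std(best["f1s"]))
    fitted.cv_precision_mean = float(np.mean(best["ps"]))
    fitted.cv_precision_std = float(np.std(best["ps"]))
    fitted.cv_recall_mean = float(np.mean(best["rs"]))
    fitted.cv_recall_std = float(np.std(best["rs"]))
    if art["classifier"] is not None:
        _, _, fitted.train_f1 = weighted_prf(y, fitted.predict(X))
    return fitted


def _artefacts_to_pipeline(art, spec, params, view, seed) -> FittedPipeline:
    return FittedPipeline(
        spec=spec,
        best_params=dict(params),
        cv_f1_mean=float("nan"),
        cv_f1_std=float("nan"),
        cv_precision_mean=float("nan"),
        cv_precision_std=float("nan"),
        cv_recall_mean=float("nan"),
        cv_recall_std=float("nan"),
        impute_means=art["impute_means"],
        var_mask=art["var_mask"],
        scaler_stats=art["scaler_stats"],
        support_mask=art["support_mask"],
        fs_scores=art["fs_scores"],
        classifier=art["classifier"],
        feature_names=list(view.feature_names),
        is_snp=view.is_snp.copy(),
        train_f1=float("nan"),
        seed=seed,
    )
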