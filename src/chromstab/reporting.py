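"""Evaluation metrics, confusion matrices, signed feature ranking and
summary tables for the experiment grid."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .pipeline_core import FittedPipeline, PipelineSpec, weighted_prf


@dataclass
class EvaluationReport:
    """Test-set metrics of one final model, plus its CV statistics.

    All per-class and overall test metrics derive from a single
    predicted-label vector; the confusion matrix is stored as
    (TN, FP, FN, TP) with class 1 treated as positive, so every metric is
    recomputable from the matrix.
    """

    cv_f1_mean: float
    cv_f1_std: float
    cv_precision_mean: float
    cv_precision_std: float
    cv_recall_mean: float
    cv_recall_std: float
    train_f1: float
    test_f1: float
    test_precision: float
    test_recall: float
    per_class: dict  # {class: {"f1","precision","recall","support"}}
    confusion: tuple  # (TN, FP, FN, TP)
    best_params: dict
    n_test: int

    def to_dict(self) -> dict:
        d = {
            "cv_f1_mean": self.cv_f1_mean,
            "cv_f1_std": self.cv_f1_std,
            "cv_precision_mean": self.cv_precision_mean,
            "cv_precision_std": self.cv_precision_std,
            "cv_recall_mean": self.cv_recall_mean,
            "cv_recall_std": self.cv_recall_std,
            "train_f1": self.train_f1,
            "test_f1": self.test_f1,
            "test_precision": self.test_precision,
            "test_recall": self.test_recall,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": {"tn": self.confusion[0], "fp": self.confusion[1],
                          "fn": self.confusion[2], "tp": self.confusion[3]},
            "best_params": self.best_params,
            "n_test": self.n_test,
        }
        return d


@dataclass
class RankedFeature:
    """One feature with its ranking metric, direction and provenance."""

    feature: str
    value: float
    sign: str  # "+", "-" or "." when the source carries no direction
    source: str  # svm_weight | rf_importance | fs_pvalue | fs_coefficient
    is_snp: bool = True


@dataclass
class ExperimentReport:
    """Outcome of one (FS, sampling, classifier) experiment."""

    name: str
    fs_method: str
    sampling: str
    classifier: str
    evaluation: EvaluationReport | None = None
    ranked_features: list = field(default_factory=list)
    stability_results: list = field(default_factory=list)
    merged_features: list = field(default_factory=list)
    selected_by_chromosome: dict = field(default_factory=dict)
    seed: int = 0
    failed: bool = False
    error: str = ""

    @property
    def cv_f1_mean(self) -> float:
        return self.evaluation.cv_f1_mean if self.evaluation else float("nan")

    def selected_snp_set(self) -> frozenset:
        return frozenset(r.feature for r in self.ranked_features if r.is_snp)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "fs_method": self.fs_method,
            "sampling": self.sampling,
            "classifier": self.classifier,
            "seed": self.seed,
            "failed": self.failed,
        }
        if self.failed:
            d["error"] = self.error
            return d
        d["evaluation"] = self.evaluation.to_dict()
        d["merged_features"] = list(self.merged_features)
        d["ranked_features"] = [
            {"feature": r.feature, "value": r.value, "sign": r.sign,
             "source": r.source, "is_snp": r.is_snp}
            for r in self.ranked_features
        ]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)


def evaluate(model: FittedPipeline, test_view) -> EvaluationReport:
    """Score a fitted pipeline on an untouched test view.

    Zero-support classes (e.g. no predicted positives) yield 0 metrics
    with a warning rather than an exception.
    """
    y_true = test_view.y
    y_pred = model.predict(test_view.X)
    labels = [0, 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
    for c, prec in zip(labels, p):
        if prec == 0.0 and (np.asarray(y_pred) == c).sum() == 0:
            warnings.warn(
                f"no predictions for class {c}; its precision/F1 reported as 0",
                stacklevel=2,
            )
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=labels).ravel()
    wp, wr, wf = weighted_prf(y_true, y_pred)
    per_class = {
        c: {
            "f1": float(f[i]), "precision": float(p[i]),
            "recall": float(r[i]), "support": int(support[i]),
        }
        for i, c in enumerate(labels)
    }
    return EvaluationReport(
        cv_f1_mean=model.cv_f1_mean,
        cv_f1_std=model.cv_f1_std,
        cv_precision_mean=model.cv_precision_mean,
        cv_precision_std=model.cv_precision_std,
        cv_recall_mean=model.cv_recall_mean,
        cv_recall_std=model.cv_recall_std,
        train_f1=model.train_f1,
        test_f1=wf,
        test_precision=wp,
        test_recall=wr,
        per_class=per_class,
        confusion=(int(tn), int(fp), int(fn), int(tp)),
        best_params=dict(model.best_params),
        n_test=len(y_true),
    )


def rank_features(model: FittedPipeline, spec: PipelineSpec) -> list[RankedFeature]:
    """Rank the final model's selected features with signs.

    Linear SVM: |weight| descending, sign of the weight.  RF: impurity
    importance descending; direction borrowed from the FS coefficient
    when the FS stage produced one, otherwise '.'.  KNN has no intrinsic
    ranking, so the FS metric is used: ANOVA p-values ascending, or
    |coefficient| descending for the regression-based selectors.
    """
    sel_idx = np.flatnonzero(model.support_mask)
    names = [model.feature_names[i] for i in sel_idx]
    is_snp = model.is_snp[sel_idx]
    fs_scores = model.fs_scores[sel_idx]
    fs = spec.fs_method
    clf_name = spec.classifier

    def _signed(values, source, descending=True):
        order = np.argsort(-np.abs(values) if descending else values, kind="stable")
        return [
            RankedFeature(
                feature=names[i],
                value=float(abs(values[i]) if descending else values[i]),
                sign="+" if values[i] > 0 else ("-" if values[i] < 0 else "."),
                source=source,
                is_snp=bool(is_snp[i]),
            )
            for i in order
        ]

    if model.classifier is None:
        return []
    if clf_name == "linear_svm":
        return _signed(model.classifier.coef_.ravel(), "svm_weight")
    if clf_name == "rf":
        imp = model.classifier.feature_importances_
        order = np.argsort(-imp, kind="stable")
        has_coef = fs in ("rfe_lr", "rlr_l1")
        out = []
        for i in order:
            if has_coef and fs_scores[i] != 0:
                sign = "+" if fs_scores[i] > 0 else "-"
            else:
                sign = "."
            out.append(
                RankedFeature(
                    feature=names[i], value=float(imp[i]), sign=sign,
                    source="rf_importance", is_snp=bool(is_snp[i]),
                )
            )
        return out
    if clf_name == "knn":
        if fs == "anova":
            order = np.argsort(fs_scores, kind="stable")  # ascending p-value
            return [
                RankedFeature(
                    feature=names[i], value=float(fs_scores[i]), sign=".",
                    source="fs_pvalue", is_snp=bool(is_snp[i]),
                )
                for i in order
            ]
        if fs in ("rfe_lr", "rlr_l1"):
            return _signed(fs_scores, "fs_coefficient")
    raise ValueError(f"no ranking rule for classifier {clf_name!r} with FS {fs!r}")


def feature_intersection_across_experiments(
    reports: list[ExperimentReport], grouping=("fs_method", "classifier")
) -> pd.DataFrame:
    """Per group of experiments sharing the grouping key (default
    FS + classifier), the cardinality of the intersection of their
    selected-SNP sets."""
    groups: dict[tuple, list] = {}
    for rep in reports:
        if rep.failed:
            continue
        key = tuple(getattr(rep, g) for g in grouping)
        groups.setdefault(key, []).append(rep)
    rows = []
    for key, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        sets = [m.selected_snp_set() for m in members]
        inter = frozenset.intersection(*sets)
        rows.append(
            {
                **dict(zip(grouping, key)),
                "n_experiments": len(members),
                "set_sizes": "/".join(str(len(s)) for s in sets),
                "n_match": len(inter),
            }
        )
    return pd.DataFrame(rows)


def summary_table(reports: list[ExperimentReport]) -> pd.DataFrame:
    """Grid summary ordered by CV F1 (descending): one row per experiment
    with CV/train/test metrics overall and per class."""
    rows = []
    for rep in reports:
        row = {
            "fs": rep.fs_method, "sampling": rep.sampling,
            "classifier": rep.classifier, "failed": rep.failed,
        }
        if not rep.failed and rep.evaluation is not None:
            ev = rep.evaluation
            row.update(
                {
                    "cv_f1_mean": ev.cv_f1_mean, "cv_f1_std": ev.cv_f1_std,
                    "cv_precision_mean": ev.cv_precision_mean,
                    "cv_precision_std": ev.cv_precision_std,
                    "cv_recall_mean": ev.cv_recall_mean,
                    "cv_recall_std": ev.cv_recall_std,
                    "train_f1": ev.train_f1, "test_f1": ev.test_f1,
                    "test_precision": ev.test_precision,
                    "test_recall": ev.test_recall,
                    "test_f1_0": ev.per_class[0]["f1"],
                    "test_precision_0": ev.per_class[0]["precision"],
                    "test_recall_0": ev.per_class[0]["recall"],
                    "test_f1_1": ev.per_class[1]["f1"],
                    "test_precision_1": ev.per_class[1]["precision"],
                    "test_recall_1": ev.per_class[1]["recall"],
                    "n_features": sum(1 for r in rep.ranked_features if r.is_snp),
                    "best_params": json.dumps(rep.evaluation.best_params, sort_keys=True),
                }
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if "cv_f1_mean" in df.columns:
        df = df.sort_values("cv_f1_mean", ascending=False, kind="stable")
    return df.reset_index(drop=True)
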