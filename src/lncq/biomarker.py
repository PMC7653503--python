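"""Diagnostic-biomarker evaluation: Gaussian naive Bayes under leave-one-out
cross-validation, scored by weighted (balanced) accuracy.

For each two-group comparison, classifiers are built from the normalized
expression values (``2**-delta_ct``) of (1) each feature alone, (2) the full
feature panel, and (3) the reduced panel of features that were significant in
that comparison.  Each sample is predicted by a model trained on all other
samples; the positive class is called when the posterior exceeds 0.5 (an
exact tie goes to the negative class), and each fold contributes one cell of
the confusion matrix.  Because group sizes are unbalanced, performance is

    WA = 1/2 * (TP/(TP+FN) + TN/(TN+FP)),

the mean of sensitivity and specificity, weighting both classes equally
regardless of their sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lncq")


@dataclass
class NBModel:
    positive_label: str
    negative_label: str
    class_priors: dict[str, float]
    means: pd.DataFrame  # class x feature
    variances: pd.DataFrame  # class x feature, floored

    @property
    def features(self) -> list[str]:
        return list(self.means.columns)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: str

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BiomarkerReport:
    comparison: str
    variant: str  # "single:<feature>" | "full" | "reduced"
    features: list[str]
    confusion: ConfusionMatrix
    weighted_accuracy: float
    fold_errors: list[str] = field(default_factory=list)


def fit_gaussian_nb(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_label: str,
    variance_floor_eps: float = 1e-9,
    min_per_class: int = 2,
) -> NBModel:
    """Fit class-conditional Gaussians per feature (samples x features input).

    Priors are the empirical class frequencies; per-class variances use the
    maximum-likelihood (ddof=0) estimator and are floored at
    ``variance_floor_eps`` times the pooled variance of the training data so
    constant features keep finite densities.  ``min_per_class`` may be
    relaxed to 1 inside cross-validation folds, where a singleton class gets
    the floored variance.
    """
    classes = labels.unique().tolist()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from labels")
    negative_label = next(c for c in classes if c != positive_label)
    counts = labels.value_counts()
    if (counts < min_per_class).any():
        raise ValueError(
            f"need >= {min_per_class} samples per class, got {counts.to_dict()}"
        )
    X = features.astype(float)
    if X.isna().any().any():
        raise ValueError("missing feature values in training data")
    global_var = float(X.to_numpy().var())
    floor = variance_floor_eps * (global_var if global_var > 0 else 1.0)
    means = X.groupby(labels).mean()
    variances = X.groupby(labels).var(ddof=0).clip(lower=floor)
    priors = (counts / counts.sum()).to_dict()
    return NBModel(
        positive_label=positive_label,
        negative_label=negative_label,
        class_priors=priors,
        means=means,
        variances=variances,
    )


def posterior_positive(model: NBModel, x: pd.Series) -> float:
    """Posterior probability of the positive class for one sample."""
    missing = [f for f in model.features if f not in x.index or pd.isna(x[f])]
    if missing:
        raise ValueError(f"missing feature values: {missing}")
    logp = {}
    for cls in (model.positive_label, model.negative_label):
        mu = model.means.loc[cls, model.features].to_numpy(float)
        var = model.variances.loc[cls, model.features].to_numpy(float)
        xv = x[model.features].to_numpy(float)
        ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + (xv - mu) ** 2 / var)
        logp[cls] = math.log(model.class_priors[cls]) + ll
    m = max(logp.values())
    num = math.exp(logp[model.positive_label] - m)
    den = num + math.exp(logp[model.negative_label] - m)
    return num / den


def predict_nb(
    model: NBModel, x: pd.Series, cutoff: float = 0.5
) -> tuple[str, float]:
    """Predict one sample; positive iff posterior strictly exceeds the
    cutoff — a posterior exactly at the cutoff yields the negative label."""
    post = posterior_positive(model, x)
    label = model.positive_label if post > cutoff else model.negative_label
    return label, post


def loo_predictions(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_label: str,
    feature_subset: list[str] | None = None,
    cutoff: float = 0.5,
    variance_floor_eps: float = 1e-9,
) -> tuple[pd.Series, list[str]]:
    """Leave-one-out predicted label per sample.

    Each fold trains on all other samples (a singleton training class is
    allowed, taking the floored variance) and predicts the left-out one.
    Folds whose training set loses a class entirely are recorded as errors in
    the returned list, not silently skipped.
    """
    n = len(labels)
    if n < 4:
        raise ValueError(f"leave-one-out needs >= 4 samples, got {n}")
    counts = labels.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError(f"need two classes with >= 2 samples each: {counts.to_dict()}")
    subset = feature_subset if feature_subset is not None else list(features.columns)
    X = features[subset]
    preds: dict = {}
    errors: list[str] = []
    for sample in X.index:
        train_idx = X.index.drop(sample)
        train_labels = labels.loc[train_idx]
        if train_labels.nunique() < 2:
            errors.append(f"fold {sample}: training set lost a class")
            continue
        model = fit_gaussian_nb(
            X.loc[train_idx], train_labels, positive_label,
            variance_floor_eps, min_per_class=1,
        )
        preds[sample], _ = predict_nb(model, X.loc[sample], cutoff)
    return pd.Series(preds, dtype=object), errors


def loo_confusion(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_label: str,
    feature_subset: list[str] | None = None,
    cutoff: float = 0.5,
    variance_floor_eps: float = 1e-9,
) -> tuple[ConfusionMatrix, list[str]]:
    """Accumulate the leave-one-out predictions into a confusion matrix, one
    cell per fold."""
    preds, errors = loo_predictions(
        features, labels, positive_label, feature_subset, cutoff, variance_floor_eps
    )
    tp = fp = tn = fn = 0
    for sample, pred in preds.items():
        if labels.loc[sample] == positive_label:
            tp += pred == positive_label
            fn += pred != positive_label
        else:
            tn += pred != positive_label
            fp += pred == positive_label
    return ConfusionMatrix(int(tp), int(fp), int(tn), int(fn), positive_label), errors


def weighted_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of sensitivity and specificity."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("weighted accuracy undefined with an empty class")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return 0.5 * (sens + spec)


def evaluate_panels(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    comparisons,
    de_tables: pd.DataFrame,
    cutoff: float = 0.5,
    feature_scale: str = "linear",
    variance_floor_eps: float = 1e-9,
) -> list[BiomarkerReport]:
    """Evaluate single-feature, full-panel and reduced-panel classifiers.

    ``expr`` is the normalized-expression matrix (features x samples,
    ``2**-delta_ct``); with ``feature_scale="log"`` the log2 values are used
    instead.  ``de_tables`` is the concatenated DE output with a
    ``comparison`` column; the reduced panel keeps the significant features
    of each comparison (omitted with a warning when none are significant,
    identical to the full panel when all are).
    """
    if feature_scale not in ("linear", "log"):
        raise ValueError(f"unknown feature_scale {feature_scale!r}")
    mat = np.log2(expr) if feature_scale == "log" else expr
    reports: list[BiomarkerReport] = []
    for comp in comparisons:
        a, b = comp.masks(metadata)
        present = set(expr.columns)
        a = [s for s in a if s in present]
        b = [s for s in b if s in present]
        if not a or not b:
            raise ValueError(f"comparison {comp.name!r}: groups absent from matrix")
        samples = a + b
        labels = pd.Series(
            ["a" if s in set(a) else "b" for s in samples], index=samples
        )
        positive = comp.positive_label
        X = mat[samples].T.dropna(axis=1)
        feats = list(X.columns)
        de = de_tables[de_tables["comparison"] == comp.name]
        sig = [f for f in feats if f in de.index[de["significant"]]]

        panels: list[tuple[str, list[str]]] = [(f"single:{f}", [f]) for f in feats]
        panels.append(("full", feats))
        if sig:
            panels.append(("reduced", sig))
        else:
            logger.warning(
                "comparison %s: no significant feature; reduced panel omitted",
                comp.name,
            )
        for variant, subset in panels:
            cm, errs = loo_confusion(
                X, labels, positive, subset, cutoff, variance_floor_eps
            )
            reports.append(
                BiomarkerReport(
                    comparison=comp.name,
                    variant=variant,
                    features=subset,
                    confusion=cm,
                    weighted_accuracy=weighted_accuracy(cm),
                    fold_errors=errs,
                )
            )
    return reports


def reports_to_frame(reports: list[BiomarkerReport]) -> pd.DataFrame:
    rows = [
        {
            "comparison": r.comparison,
            "variant": r.variant,
            "features": ",".join(r.features),
            "TP": r.confusion.tp,
            "FP": r.confusion.fp,
            "TN": r.confusion.tn,
            "FN": r.confusion.fn,
            "weighted_accuracy": r.weighted_accuracy,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
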