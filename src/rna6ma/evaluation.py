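"""Evaluation metrics and the two assessment protocols.

Metrics: sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy ACC, Matthews correlation coefficient MCC, F1, and AUROC (the
Mann-Whitney probability that a random positive outscores a random
negative, ties counting one half). Ratios with a zero denominator are
reported as explicitly undefined, never silently coerced to 0.

Protocols: a single stratified independent train/test split (default
70/30) and stratified k-fold cross-validation (default k = 10) whose
headline numbers pool the confusion counts across folds, with per-fold
metrics retained for dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import ensembles
from .encodings import encode_dataset
from .ensembles import ModelConfig
from .windows import WindowDataset, stratified_split


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally with class 1 = 6mA site."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion(labels, calls) -> ConfusionCounts:
    """Tally a binary label/call pair into confusion counts."""
    y = np.asarray(labels, dtype=int)
    c = np.asarray(calls, dtype=int)
    if y.shape != c.shape:
        raise ValueError("labels and calls must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (c == 1))),
        tn=int(np.sum((y == 0) & (c == 0))),
        fp=int(np.sum((y == 0) & (c == 1))),
        fn=int(np.sum((y == 1) & (c == 0))),
    )


@dataclass
class MetricsReport:
    """Confusion counts plus the scalar metrics of one evaluation.

    Undefined metrics are ``None`` with the reason recorded in
    ``undefined``.
    """

    counts: ConfusionCounts
    sn: float | None
    sp: float | None
    acc: float | None
    mcc: float | None
    f1: float | None
    auroc: float | None = None
    protocol: str = "independent"
    undefined: dict[str, str] = field(default_factory=dict)
    per_fold: list[dict[str, Any]] = field(default_factory=list)
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    details: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "protocol": self.protocol,
            "counts": {"TP": self.counts.tp, "TN": self.counts.tn,
                       "FP": self.counts.fp, "FN": self.counts.fn},
            "Sn": self.sn, "Sp": self.sp, "ACC": self.acc,
            "MCC": self.mcc, "F1": self.f1, "AUROC": self.auroc,
            "undefined": self.undefined,
            "per_fold": self.per_fold,
            "roc_points": [list(p) for p in self.roc_points],
            "details": self.details,
        }


def _ratio(num: int, den: int, name: str, undefined: dict[str, str]):
    if den == 0:
        undefined[name] = "zero denominator"
        return None
    return num / den


def metrics(counts: ConfusionCounts, protocol: str = "independent") -> MetricsReport:
    """Scalar metrics of a confusion table (AUROC requires scores)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: dict[str, str] = {}
    sn = _ratio(tp, tp + fn, "Sn", undefined)
    sp = _ratio(tn, tn + fp, "Sp", undefined)
    acc = _ratio(tp + tn, counts.total, "ACC", undefined)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1", undefined)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        undefined["MCC"] = "zero denominator"
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)
    return MetricsReport(
        counts=counts, sn=sn, sp=sp, acc=acc, mcc=mcc, f1=f1,
        protocol=protocol, undefined=undefined,
    )


def roc_auc(labels, scores) -> tuple[float, list[tuple[float, float]]]:
    """AUROC and (FPR, TPR) curve points for continuous scores."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    auroc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auroc, list(zip(fpr.tolist(), tpr.tolist()))


def _score_report(labels, scores, protocol: str) -> MetricsReport:
    calls = (np.asarray(scores) >= 0.5).astype(int)
    report = metrics(confusion(labels, calls), protocol=protocol)
    report.auroc, report.roc_points = roc_auc(labels, scores)
    return report


def independent_test(
    config: ModelConfig,
    ds: WindowDataset,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> MetricsReport:
    """Encode, split, train on the training part, report on the test part."""
    train_ds, test_ds = stratified_split(ds, test_fraction, seed=seed)
    train_ids = {w.id for w in train_ds}
    test_ids = {w.id for w in test_ds}
    assert not train_ids & test_ids, "train/test partitions overlap"
    model = ensembles.train(config, encode_dataset(train_ds))
    test_table = encode_dataset(test_ds)
    report = _score_report(
        test_table["label"].to_numpy(),
        model.predict_scores(test_table),
        protocol="independent",
    )
    report.details = {
        "n_train": len(train_ds),
        "n_test": len(test_ds),
        "disjoint": True,
        "test_fraction": test_fraction,
        "seed": seed,
        "family": config.family,
        "variant": config.variant,
    }
    return report


def kfold_cv(
    config: ModelConfig,
    ds: WindowDataset,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold CV; pooled counts headline, per-fold retained."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = ds.class_counts()
    if min(counts.values()) < k:
        raise ValueError(f"each class needs >= {k} members, got {counts}")
    table = encode_dataset(ds)
    y = table["label"].to_numpy()
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores = np.zeros(len(y))
    per_fold: list[dict[str, Any]] = []
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        model = ensembles.train(config, table.iloc[tr])
        scores = model.predict_scores(table.iloc[te])
        all_scores[te] = scores
        fold_report = _score_report(y[te], scores, protocol="fold")
        pooled = pooled + fold_report.counts
        per_fold.append(
            {"fold": fold, "n_test": int(len(te)),
             "Sn": fold_report.sn, "Sp": fold_report.sp,
             "ACC": fold_report.acc, "MCC": fold_report.mcc,
             "F1": fold_report.f1, "AUROC": fold_report.auroc}
        )
    report = metrics(pooled, protocol=f"kfold({k})")
    report.auroc, report.roc_points = roc_auc(y, all_scores)
    report.per_fold = per_fold
    report.details = {
        "k": k, "seed": seed, "n": len(y),
        "family": config.family, "variant": config.variant,
    }
    return report
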