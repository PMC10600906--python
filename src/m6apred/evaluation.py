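"""Metrics from first principles, stratified k-fold CV, and transfer testing.

Acc, Sens, Spec and MCC are computed directly from the 2x2 confusion table;
AUC is the rank-based (Mann-Whitney) statistic with ties counted 1/2, which
equals the trapezoidal ROC area. Any metric with a zero denominator is
reported as 0 and flagged as degenerate so reports stay serializable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import modeling
from .encoders import EncodingScheme, FeatureMatrix, encode_dataset
from .errors import (
    DimensionError,
    EmptyEvaluationError,
    HeterogeneousLengthError,
    StratificationError,
    UndefinedAUCError,
)
from .modeling import ModelSpec
from .seqio import SequenceRecord, normalize_alphabet

METRIC_NAMES = ("acc", "sens", "spec", "mcc", "auc")

# families whose feature columns are tied to absolute sequence positions
POSITIONAL_FAMILIES = ("binary", "enac", "ncp")


@dataclass(frozen=True)
class ConfusionCounts:
    """Standard 2x2 tabulation with class 1 = positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Threshold metrics for one evaluation; ``degenerate`` names any metric
    whose denominator was zero (reported as 0)."""

    acc: float
    sens: float
    spec: float
    mcc: float
    degenerate: tuple[str, ...] = ()


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise DimensionError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise EmptyEvaluationError("empty label vectors")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Acc, Sens, Spec and MCC from a confusion table.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise EmptyEvaluationError("confusion table is empty")
    degenerate: list[str] = []
    acc = (tp + tn) / total
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        sens = 0.0
        degenerate.append("sens")
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        spec = 0.0
        degenerate.append("spec")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom > 0:
        mcc = (tp * tn - fp * fn) / denom
    else:
        mcc = 0.0
        degenerate.append("mcc")
    return MetricSet(acc=acc, sens=sens, spec=spec, mcc=mcc, degenerate=tuple(degenerate))


def auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    yt = np.asarray(y_true, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if yt.shape != sc.shape:
        raise DimensionError(f"length mismatch: {yt.shape} vs {sc.shape}")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC requires both classes present")
    ranks = rankdata(sc)  # average ranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[yt == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def stratified_fold_indices(
    labels: Sequence[int], k: int, seed: int
) -> np.ndarray:
    """Assign each record a fold in 0..k-1: per-class seeded shuffle, then
    round-robin, so per-class counts across folds differ by at most 1."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = np.empty(labels.size, dtype=int)
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size < k:
            raise StratificationError(
                f"class {cls} has {members.size} members < k = {k}"
            )
        rng.shuffle(members)
        folds[members] = np.arange(members.size) % k
    return folds


def stratified_kfold(
    records: Sequence[SequenceRecord], k: int, seed: int
) -> np.ndarray:
    """Fold assignment (one integer per record) for a labeled record list."""
    return stratified_fold_indices([r.label for r in records], k, seed)


@dataclass
class FoldResult:
    counts: ConfusionCounts
    acc: float
    sens: float
    spec: float
    mcc: float
    auc: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "acc": self.acc,
            "sens": self.sens,
            "spec": self.spec,
            "mcc": self.mcc,
            "auc": self.auc,
            "degenerate": list(self.degenerate),
        }


@dataclass
class EvaluationReport:
    """Per-fold and aggregate results of one (scheme, model, protocol) run."""

    per_fold: list[FoldResult]
    aggregate: dict[str, float]
    scheme: EncodingScheme
    model: ModelSpec
    protocol: str  # "cv" | "transfer"
    seed: int
    pooled: dict[str, float] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "protocol": self.protocol,
                "scheme": self.scheme.name,
                "model": self.model.as_dict(),
                "seed": self.seed,
                "aggregate": self.aggregate,
                "pooled": self.pooled,
                "per_fold": [f.as_dict() for f in self.per_fold],
            },
            indent=2,
        )

    def csv_row(self, species: str = "") -> dict:
        row = {
            "species": species,
            "scheme": self.scheme.family,
            "param": "" if self.scheme.param is None else self.scheme.param,
            "model": self.model.family,
            "tuned": self.model.tuned,
            "protocol": self.protocol,
        }
        row.update({m: self.aggregate[m] for m in METRIC_NAMES})
        row["seed"] = self.seed
        return row


def _evaluate_split(y_true: np.ndarray, scores: np.ndarray) -> FoldResult:
    y_pred = (scores >= 0.5).astype(int)
    counts = confusion(y_true, y_pred)
    m = metrics(counts)
    degenerate = list(m.degenerate)
    try:
        a = auc(y_true, scores)
    except UndefinedAUCError:
        a = 0.0
        degenerate.append("auc")
    return FoldResult(
        counts=counts,
        acc=m.acc,
        sens=m.sens,
        spec=m.spec,
        mcc=m.mcc,
        auc=a,
        degenerate=tuple(degenerate),
    )


def _aggregate(per_fold: list[FoldResult]) -> dict[str, float]:
    return {
        m: float(np.mean([getattr(f, m) for f in per_fold])) for m in METRIC_NAMES
    }


def _pooled(per_fold: list[FoldResult]) -> dict[str, float]:
    """Alternative aggregation: sum the confusion counts, then compute
    threshold metrics once (AUC is not poolable and repeats the mean)."""
    tot = ConfusionCounts(
        tp=sum(f.counts.tp for f in per_fold),
        tn=sum(f.counts.tn for f in per_fold),
        fp=sum(f.counts.fp for f in per_fold),
        fn=sum(f.counts.fn for f in per_fold),
    )
    m = metrics(tot)
    return {
        "acc": m.acc,
        "sens": m.sens,
        "spec": m.spec,
        "mcc": m.mcc,
        "auc": float(np.mean([f.auc for f in per_fold])),
    }


def cross_validate_matrix(
    X: FeatureMatrix,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    include_pooled: bool = False,
) -> EvaluationReport:
    """Stratified k-fold CV on an already-encoded feature matrix."""
    folds = stratified_fold_indices(X.labels, k, seed)
    per_fold = []
    for f in range(k):
        train = folds != f
        test = ~train
        X_train = FeatureMatrix(
            values=X.values[train],
            scheme=X.scheme,
            feature_names=X.feature_names,
            record_ids=[i for i, t in zip(X.record_ids, train) if t],
            labels=X.labels[train],
        )
        model = modeling.fit(spec, X_train)
        scores = modeling.predict_scores(
            model,
            FeatureMatrix(
                values=X.values[test],
                scheme=X.scheme,
                feature_names=X.feature_names,
                record_ids=[i for i, t in zip(X.record_ids, test) if t],
                labels=X.labels[test],
            ),
        )
        per_fold.append(_evaluate_split(X.labels[test], scores))
    return EvaluationReport(
        per_fold=per_fold,
        aggregate=_aggregate(per_fold),
        scheme=X.scheme,
        model=spec,
        protocol="cv",
        seed=seed,
        pooled=_pooled(per_fold) if include_pooled else None,
    )


def cross_validate(
    records: Sequence[SequenceRecord],
    scheme: EncodingScheme,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    include_pooled: bool = False,
) -> EvaluationReport:
    """Encode the records with the scheme, then run stratified k-fold CV.

    Encoding is per-sequence (no cross-record statistics), so it is done once
    for the whole dataset without information leakage across folds.
    """
    X = encode_dataset(records, scheme)
    return cross_validate_matrix(X, spec, k=k, seed=seed, include_pooled=include_pooled)


def cross_species(
    train: Sequence[SequenceRecord],
    test: Sequence[SequenceRecord],
    scheme: EncodingScheme,
    spec: ModelSpec,
) -> EvaluationReport:
    """Fit once on all training records, evaluate once on all test records.

    Alphabets are normalized to the training set's before encoding. For
    positional schemes (binary, enac, ncp) the two sets must share a length.
    """
    train_len = {len(r.sequence) for r in train}
    test_len = {len(r.sequence) for r in test}
    if scheme.family in POSITIONAL_FAMILIES and train_len != test_len:
        raise HeterogeneousLengthError(
            f"positional scheme {scheme.name}: train length {sorted(train_len)} "
            f"!= test length {sorted(test_len)}"
        )
    target = train[0].alphabet
    train = normalize_alphabet(train, target)
    test = normalize_alphabet(test, target)
    X_train = encode_dataset(train, scheme)
    X_test = encode_dataset(test, scheme)
    model = modeling.fit(spec, X_train)
    scores = modeling.predict_scores(model, X_test)
    result = _evaluate_split(X_test.labels, scores)
    return EvaluationReport(
        per_fold=[result],
        aggregate=_aggregate([result]),
        scheme=scheme,
        model=spec,
        protocol="transfer",
        seed=spec.seed,
    )
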