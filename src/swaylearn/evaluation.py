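"""Participant-level stratified cross-validation and confusion metrics.

Folds are made at the participant level (all of a participant's windows and
poses stay on one side of the split) with class proportions preserved to
within one participant per fold. Metrics treat ASD as the positive class:
precision, recall (sensitivity), specificity, Matthews correlation
coefficient and F1. Fold averages are unweighted means.

Two differential experiments are provided: an x-y projection that drops all
joint z-channels (a markerless single-camera depth estimate is the least
trustworthy axis), and a balanced subsample equalising the group sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import ASD, TD, ClassificationResult, EnsembleModel, ForestParams, classify_participant, train_ensemble
from .dataio import RawRecording
from .errors import ConfigurationError, TrainingError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with ASD as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    specificity: float
    mcc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "f1": self.f1,
        }


def _ratio(num: float, den: float) -> float:
    """0/0 -> 0 by convention (logged once per call site via debug)."""
    if den == 0:
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Standard binary-classification metrics from confusion counts.

    Any 0/0 ratio (including a zero MCC denominator) is reported as 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = _ratio(2.0 * precision * recall, precision + recall)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, denom)
    return MetricSet(precision=precision, recall=recall, specificity=specificity,
                     mcc=mcc, f1=f1)


def average_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    """Unweighted mean of each metric over folds."""
    arr = np.array([[m.precision, m.recall, m.specificity, m.mcc, m.f1]
                    for m in metric_sets])
    mean = arr.mean(axis=0)
    return MetricSet(*mean.tolist())


def stratified_folds(
    labels: dict[str, str], k: int, seed: int = 0
) -> dict[str, int]:
    """Assign participants to k folds preserving the ASD:TD ratio (+/-1).

    k = 1 is allowed as a degenerate single fold (with a warning); k larger
    than the smaller class is a configuration error.
    """
    pids = sorted(labels)
    y = [labels[p] for p in pids]
    class_sizes = pd.Series(y).value_counts()
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k == 1:
        logger.warning("k=1: single degenerate fold containing every participant")
        return {p: 0 for p in pids}
    if k > class_sizes.min():
        raise ConfigurationError(
            f"k={k} exceeds the smaller class size {class_sizes.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(pids)), y)):
        for i in test_idx:
            assignment[pids[i]] = fold
    return assignment


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: MetricSet
    results: list[ClassificationResult]
    top_features: list[str] = field(default_factory=list)


@dataclass
class CVResult:
    k: int
    fold_assignments: dict[str, int]
    folds: list[FoldResult]
    averages: MetricSet
    #: Out-of-fold boundary distance per participant.
    distances: dict[str, float]
    labels: dict[str, str]
    predictions: dict[str, str]

    def to_table(self) -> pd.DataFrame:
        """Fold-by-fold metric table plus an unweighted 'Average' row."""
        rows = []
        for fr in self.folds:
            c = fr.counts
            rows.append({
                "fold": fr.fold + 1,
                "precision": fr.metrics.precision,
                "recall": fr.metrics.recall,
                "specificity": fr.metrics.specificity,
                "mcc": fr.metrics.mcc,
                "f1": fr.metrics.f1,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            })
        avg = self.averages
        rows.append({
            "fold": "average",
            "precision": avg.precision, "recall": avg.recall,
            "specificity": avg.specificity, "mcc": avg.mcc, "f1": avg.f1,
            "tp": "", "fp": "", "tn": "", "fn": "",
        })
        return pd.DataFrame(rows)


def counts_from_results(
    results: list[ClassificationResult], labels: dict[str, str]
) -> ConfusionCounts:
    tp = fp = tn = fn = 0
    for r in results:
        truth, pred = labels[r.participant_id], r.final_label
        if truth == ASD:
            tp += pred == ASD
            fn += pred == TD
        else:
            tn += pred == TD
            fp += pred == ASD
    return ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def run_cv(
    features: list[FeatureMatrix],
    labels: dict[str, str],
    k: int = 5,
    seed: int = 0,
    params: ForestParams | None = None,
    top_k_features: int = 20,
) -> CVResult:
    """Stratified k-fold CV of the pose ensemble at the participant level.

    For each fold an ensemble is trained on the remaining participants'
    vectors and applied to the held-out participants; confusion counts,
    metrics and the fold model's top-ranked features are recorded, and each
    participant's boundary distance is taken from the fold holding it out.
    """
    from .interpretation import top_k, total_mdi

    params = params or ForestParams()
    present = {fm.participant_id for fm in features}
    labels = {p: g for p, g in labels.items() if p in present}
    assignment = stratified_folds(labels, k, seed)
    folds: list[FoldResult] = []
    distances: dict[str, float] = {}
    predictions: dict[str, str] = {}
    for fold in range(max(assignment.values()) + 1):
        test_pids = {p for p, f in assignment.items() if f == fold}
        train_fms = [fm for fm in features if fm.participant_id not in test_pids]
        test_fms = [fm for fm in features if fm.participant_id in test_pids]
        train_classes = {labels[fm.participant_id] for fm in train_fms}
        if len(train_classes) < 2:
            raise TrainingError(f"fold {fold}: training participants are single-class")
        fold_params = params.with_(rng_seed=params.rng_seed + 101 * (fold + 1))
        model = train_ensemble(train_fms, labels, fold_params)
        by_pid: dict[str, list[FeatureMatrix]] = {}
        for fm in test_fms:
            by_pid.setdefault(fm.participant_id, []).append(fm)
        results = [classify_participant(model, fms) for _, fms in sorted(by_pid.items())]
        for r in results:
            distances[r.participant_id] = r.boundary_distance
            predictions[r.participant_id] = r.final_label
        counts = counts_from_results(results, labels)
        folds.append(
            FoldResult(
                fold=fold,
                counts=counts,
                metrics=metrics(counts),
                results=results,
                top_features=top_k(total_mdi(model), top_k_features),
            )
        )
    averages = average_metrics([fr.metrics for fr in folds])
    logger.info("%d-fold CV: mean MCC %.3f, mean F1 %.3f", k, averages.mcc, averages.f1)
    return CVResult(
        k=k,
        fold_assignments=assignment,
        folds=folds,
        averages=averages,
        distances=distances,
        labels=labels,
        predictions=predictions,
    )


def project_xy(recordings: list[RawRecording]) -> list[RawRecording]:
    """Drop every joint z-channel (board channels kept): 62 -> 42 channels.

    Downstream feature vectors then have length 84.
    """
    out = []
    for rec in recordings:
        keep = [i for i, name in enumerate(rec.channel_names) if not name.endswith(":z")]
        out.append(
            RawRecording(
                participant_id=rec.participant_id,
                session=rec.session,
                pose_id=rec.pose_id,
                data=rec.data[:, keep],
                channel_names=[rec.channel_names[i] for i in keep],
                frame_rate_hz=rec.frame_rate_hz,
            )
        )
    return out


def balance_groups(
    features: list[FeatureMatrix],
    labels: dict[str, str],
    n_per_group: int,
    seed: int = 0,
) -> tuple[list[FeatureMatrix], dict[str, str]]:
    """Equalise group sizes by subsampling the larger (ASD) group.

    Keeps every participant of the smaller group and a uniform random
    subset of the other; returns the filtered features and labels.
    """
    pids_by_group: dict[str, list[str]] = {}
    present = {fm.participant_id for fm in features}
    for pid in sorted(present):
        pids_by_group.setdefault(labels[pid], []).append(pid)
    for group, pids in pids_by_group.items():
        if n_per_group > len(pids):
            raise ConfigurationError(
                f"n_per_group={n_per_group} exceeds {group} group size {len(pids)}"
            )
    rng = np.random.default_rng(seed)
    keep: set[str] = set()
    for group, pids in pids_by_group.items():
        if len(pids) == n_per_group:
            keep.update(pids)
        else:
            keep.update(rng.choice(pids, size=n_per_group, replace=False).tolist())
    kept_features = [fm for fm in features if fm.participant_id in keep]
    kept_labels = {p: g for p, g in labels.items() if p in keep}
    return kept_features, kept_labels
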