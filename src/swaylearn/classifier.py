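"""Pose-indexed random-forest ensemble with hierarchical majority voting.

One random forest (10 CART trees by default) is trained per pose on the
feature vectors of that pose only. A participant is classified in two
voting stages: within each pose, every window vector votes ASD iff its
forest score exceeds 0.5 and the pose's partial decision is the majority
vote; across poses, the final label is the majority of the pose decisions.
Ties break toward ASD (the positive class) at both levels.

Alongside the discrete label the ensemble reports a continuous ASD
probability p — the mean over available poses of the mean vector score —
and the boundary distance 2p - 1 in [-1, +1], the individual-difference
measure correlated with age and clinical covariates downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, DomainError, TrainingError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

ASD, TD = "ASD", "TD"
_LABEL_CODE = {TD: 0, ASD: 1}


@dataclass(frozen=True)
class ForestParams:
    """CART/forest hyperparameters (Gini splitting, bootstrap resampling)."""

    n_trees: int = 10
    max_depth: int | None = None
    min_samples_leaf: int = 5
    #: Features considered per split; None = floor(sqrt(n_features)).
    features_per_split: int | None = None
    bootstrap: bool = True
    rng_seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_samples_leaf < 1:
            raise ConfigurationError("min_samples_leaf must be >= 1")
        if self.features_per_split is not None:
            if self.features_per_split < 1:
                raise ConfigurationError("features_per_split must be >= 1")
            if n_features is not None and self.features_per_split > n_features:
                raise ConfigurationError(
                    f"features_per_split exceeds feature count {n_features}"
                )

    def with_(self, **kwargs) -> "ForestParams":
        params = replace(self, **kwargs)
        params.validate()
        return params


@dataclass
class ClassificationResult:
    """Per-participant output of the two-level vote."""

    participant_id: str
    pose_decisions: dict[int, str]
    pose_probabilities: dict[int, float]
    final_label: str
    asd_probability: float
    #: asd_probability rescaled to [-1, +1]; positive side = ASD.
    boundary_distance: float
    #: Fraction of pose decisions voting ASD (the vote-based alternative
    #: continuous measure; reported alongside the score-based probability).
    asd_vote_fraction: float


@dataclass
class EnsembleModel:
    """One trained forest per pose plus the feature schema and metadata."""

    forests: dict[int, RandomForestClassifier]
    feature_names: list[str]
    params: ForestParams
    training_participants: list[str] = field(default_factory=list)

    @property
    def pose_ids(self) -> list[int]:
        return sorted(self.forests)


def train_pose_forest(
    vectors: np.ndarray,
    labels: list[str] | np.ndarray,
    params: ForestParams | None = None,
    pose_id: int | None = None,
) -> RandomForestClassifier:
    """Fit one pose's forest on its stacked window vectors.

    Both classes must be present; the trees retain per-node impurity
    decreases, from which the forest exposes normalized mean-decrease-in-
    impurity feature importances.
    """
    params = params or ForestParams()
    vectors = np.asarray(vectors, dtype=float)
    params.validate(n_features=vectors.shape[1])
    y = np.asarray([_LABEL_CODE[l] for l in labels])
    if len(np.unique(y)) < 2:
        where = f" for pose {pose_id}" if pose_id is not None else ""
        raise TrainingError(f"training data{where} contains a single class")
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        criterion="gini",
        max_depth=params.max_depth,
        min_samples_leaf=params.min_samples_leaf,
        max_features=params.features_per_split or "sqrt",
        bootstrap=params.bootstrap,
        random_state=params.rng_seed,
    )
    forest.fit(vectors, y)
    return forest


def score_vector(forest: RandomForestClassifier, vector: np.ndarray) -> float:
    """Mean over trees of the leaf ASD fraction for one feature vector."""
    return float(score_vectors(forest, np.asarray(vector, dtype=float)[None, :])[0])


def score_vectors(forest: RandomForestClassifier, vectors: np.ndarray) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != forest.n_features_in_:
        raise DomainError(
            f"expected vectors with {forest.n_features_in_} features, "
            f"got shape {vectors.shape}"
        )
    proba = forest.predict_proba(vectors)
    asd_col = list(forest.classes_).index(_LABEL_CODE[ASD])
    return proba[:, asd_col]


def decide_pose(
    forest: RandomForestClassifier, vectors: np.ndarray
) -> tuple[str, float]:
    """Partial decision for one participant-pose from all its vectors.

    Each vector votes ASD iff its score >= 0.5 (a score exactly on the
    boundary counts as ASD); the label is the vote majority with ties to
    ASD; the pose probability is the mean vector score.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 1:
        raise DomainError("decide_pose needs at least one vector")
    scores = score_vectors(forest, vectors)
    asd_votes = int((scores >= 0.5).sum())
    label = ASD if asd_votes * 2 >= len(scores) else TD
    return label, float(scores.mean())


def train_ensemble(
    features: list[FeatureMatrix],
    labels: dict[str, str],
    params: ForestParams | None = None,
) -> EnsembleModel:
    """Train one forest per pose present in the feature set.

    Each pose's forest gets its own seed derived from ``params.rng_seed``
    so forests are independent but the whole ensemble is reproducible.
    """
    params = params or ForestParams()
    if not features:
        raise TrainingError("no feature matrices to train on")
    feature_names = features[0].feature_names
    by_pose: dict[int, list[FeatureMatrix]] = {}
    for fm in features:
        by_pose.setdefault(fm.pose_id, []).append(fm)
    forests: dict[int, RandomForestClassifier] = {}
    for pose_id in sorted(by_pose):
        fms = by_pose[pose_id]
        X = np.vstack([fm.vectors for fm in fms])
        y = np.concatenate(
            [[labels[fm.participant_id]] * fm.n_windows for fm in fms]
        )
        pose_params = params.with_(rng_seed=params.rng_seed + pose_id)
        forests[pose_id] = train_pose_forest(X, y, pose_params, pose_id=pose_id)
    logger.info(
        "trained %d pose forests on %d participants",
        len(forests), len({fm.participant_id for fm in features}),
    )
    return EnsembleModel(
        forests=forests,
        feature_names=list(feature_names),
        params=params,
        training_participants=sorted({fm.participant_id for fm in features}),
    )


def classify_participant(
    model: EnsembleModel, features: list[FeatureMatrix]
) -> ClassificationResult:
    """Two-level majority vote over one participant's feature matrices.

    Vectors from different sessions of the same pose are pooled. Poses
    absent from the input (e.g. every file discarded in QC) are omitted
    from both the vote and the probability.
    """
    if not features:
        raise DomainError("no feature matrices supplied")
    pid = features[0].participant_id
    by_pose: dict[int, list[np.ndarray]] = {}
    for fm in features:
        if fm.participant_id != pid:
            raise DomainError("classify_participant received mixed participants")
        if fm.pose_id in model.forests and fm.n_windows > 0:
            by_pose.setdefault(fm.pose_id, []).append(fm.vectors)
    if not by_pose:
        raise DomainError(f"participant {pid} has no usable pose data")
    decisions: dict[int, str] = {}
    probabilities: dict[int, float] = {}
    for pose_id in sorted(by_pose):
        vectors = np.vstack(by_pose[pose_id])
        label, prob = decide_pose(model.forests[pose_id], vectors)
        decisions[pose_id] = label
        probabilities[pose_id] = prob
    asd_votes = sum(1 for l in decisions.values() if l == ASD)
    final = ASD if asd_votes * 2 >= len(decisions) else TD
    p = float(np.mean(list(probabilities.values())))
    return ClassificationResult(
        participant_id=pid,
        pose_decisions=decisions,
        pose_probabilities=probabilities,
        final_label=final,
        asd_probability=p,
        boundary_distance=2.0 * p - 1.0,
        asd_vote_fraction=asd_votes / len(decisions),
    )
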