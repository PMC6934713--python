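"""End-to-end orchestration helpers used by the CLI, tests and scripts.

The disk-based flow (simulate -> files -> clean -> featurize -> cv) is
exposed through :mod:`swaylearn.cli`; this module provides the equivalent
in-memory flow, streaming one simulated recording at a time through
cleaning so the full raw cohort never has to be held in memory at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classifier import EnsembleModel, ForestParams, train_ensemble
from .cleaning import CleaningConfig, QCReport, clean_recording, variance_qc
from .evaluation import CVResult, run_cv
from .features import FeatureConfig, FeatureMatrix, featurize_dataset
from .interpretation import (
    correlation_report,
    effect_size_report,
    fold_consistency,
    top_k,
    total_mdi,
)
from .synthetic import ParticipantProfile, SimulationConfig, iter_cohort_recordings, sample_cohort

logger = logging.getLogger(__name__)


@dataclass
class SyntheticFeatures:
    """Featurized synthetic cohort plus ground truth for calibration checks."""

    features: list[FeatureMatrix]
    profiles: list[ParticipantProfile]
    qc_report: QCReport
    #: (participant, session, pose) keys of files the simulator corrupted.
    corrupt_keys: set[tuple[str, int, int]]

    @property
    def labels(self) -> dict[str, str]:
        return {p.participant_id: p.group for p in self.profiles}

    def covariates(self) -> pd.DataFrame:
        rows = [vars(p) for p in self.profiles]
        return pd.DataFrame(rows).set_index("participant_id").drop(columns=["group", "sex"])


def simulate_features(
    sim_config: SimulationConfig,
    cleaning_config: CleaningConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> SyntheticFeatures:
    """Simulate, clean and featurize a cohort without touching disk."""
    cleaning_config = cleaning_config or CleaningConfig()
    feature_config = feature_config or FeatureConfig()
    profiles = sample_cohort(sim_config)
    cleaned = []
    corrupt_keys: set[tuple[str, int, int]] = set()
    for _, rec, corrupted in iter_cohort_recordings(sim_config, profiles):
        if corrupted:
            corrupt_keys.add(rec.key())
        cleaned.append(clean_recording(rec, cleaning_config))
    kept, qc_report = variance_qc(cleaned, cleaning_config.qc_tail)
    features = featurize_dataset(kept, feature_config)
    return SyntheticFeatures(
        features=features,
        profiles=profiles,
        qc_report=qc_report,
        corrupt_keys=corrupt_keys,
    )


def qc_scores(qc_report: QCReport, corrupt_keys: set[tuple[str, int, int]]) -> dict[str, float]:
    """Recall and false-discard rate of variance QC vs simulator ground truth."""
    discarded = qc_report.discarded_keys()
    n_corrupt = len(corrupt_keys)
    n_clean = qc_report.n_input - n_corrupt
    recall = len(discarded & corrupt_keys) / n_corrupt if n_corrupt else float("nan")
    false_rate = len(discarded - corrupt_keys) / n_clean if n_clean else 0.0
    return {"recall": recall, "false_discard_rate": false_rate,
            "n_corrupt": n_corrupt, "n_discarded": len(discarded)}


@dataclass
class StudyResult:
    """Everything one synthetic study run produces."""

    cv: CVResult
    full_model: EnsembleModel
    ranking: pd.Series
    top_features: list[str]
    overlap: float
    effect_sizes: pd.DataFrame
    correlations: pd.DataFrame
    qc: dict[str, float]
    data: SyntheticFeatures = field(repr=False, default=None)


def run_study(
    sim_config: SimulationConfig,
    cleaning_config: CleaningConfig | None = None,
    feature_config: FeatureConfig | None = None,
    params: ForestParams | None = None,
    k: int = 5,
    cv_seed: int = 0,
    top_k_features: int = 20,
) -> StudyResult:
    """Full synthetic study: simulate, clean, featurize, CV, interpret."""
    params = params or ForestParams()
    data = simulate_features(sim_config, cleaning_config, feature_config)
    cv = run_cv(data.features, data.labels, k=k, seed=cv_seed, params=params,
                top_k_features=top_k_features)
    full_model = train_ensemble(data.features, data.labels, params)
    ranking = total_mdi(full_model)
    top = top_k(ranking, top_k_features)
    overlap = fold_consistency([fr.top_features for fr in cv.folds], top)
    effects = effect_size_report(data.features, data.labels, feature_subset=top)
    correlations = correlation_report(cv.distances, data.covariates())
    return StudyResult(
        cv=cv,
        full_model=full_model,
        ranking=ranking,
        top_features=top,
        overlap=overlap,
        effect_sizes=effects,
        correlations=correlations,
        qc=qc_scores(data.qc_report, data.corrupt_keys),
        data=data,
    )
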