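"""Model interpretation: feature importance, effect sizes, correlates.

Feature importance is mean decrease in impurity (MDI): within each pose
forest the per-feature importances are normalized to sum to one, and a
feature's total score is the sum of its normalized importances across the
pose forests — so totals lie in [0, n_poses] and a score of, say, 0.6
means the feature carries 6% of the impurity reduction of the whole
ensemble on average per forest.

Group differences on individual features are summarised by Cohen's d on
per-participant means (one value per participant, avoiding
pseudo-replication across windows), and the continuous classifier output
(boundary distance) is correlated with covariates by Pearson and Spearman.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ASD, TD, EnsembleModel
from .errors import DomainError, TrainingError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)


def total_mdi(model: EnsembleModel) -> pd.Series:
    """Total normalized MDI per feature, summed over the pose forests.

    Sorted descending; ties broken by canonical feature-name order. Each
    forest's importances sum to 1, so totals lie in [0, n_forests].
    """
    if not model.forests:
        raise TrainingError("model has no trained forests")
    total = np.zeros(len(model.feature_names))
    for pose_id in model.pose_ids:
        imp = model.forests[pose_id].feature_importances_
        s = imp.sum()
        if s > 0:
            imp = imp / s
        total += imp
    series = pd.Series(total, index=model.feature_names, name="total_mdi")
    order = sorted(range(len(series)), key=lambda i: (-series.iloc[i], series.index[i]))
    return series.iloc[order]


def top_k(ranking: pd.Series, k: int) -> list[str]:
    """First k feature names by descending total MDI."""
    if k <= 0:
        raise DomainError("k must be positive")
    if k > len(ranking):
        raise DomainError(f"k={k} exceeds the number of features {len(ranking)}")
    return list(ranking.index[:k])


def list_overlap(list_a: list[str], list_b: list[str]) -> float:
    """|A intersect B| / k for two equally sized feature lists."""
    if len(list_a) != len(list_b):
        raise DomainError("overlap requires equally sized lists")
    if not list_a:
        raise DomainError("overlap of empty lists is undefined")
    return len(set(list_a) & set(list_b)) / len(list_a)


def fold_consistency(
    fold_top_lists: list[list[str]], overall_top: list[str]
) -> float:
    """Mean overlap of each fold's top-k list with the overall top-k list."""
    return float(np.mean([list_overlap(t, overall_top) for t in fold_top_lists]))


def participant_feature_means(features: list[FeatureMatrix]) -> pd.DataFrame:
    """Mean feature vector per participant (windows pooled across files)."""
    frames = [fm.to_frame() for fm in features]
    long = pd.concat(frames, ignore_index=True)
    cols = [c for c in long.columns if c not in ("participant_id", "session", "pose_id")]
    return long.groupby("participant_id")[cols].mean()


def cohens_d(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Standardized mean difference (a - b) with (n-1)-weighted pooled SD.

    Returns NaN when the pooled SD is zero (undefined effect size).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("cohens_d needs at least two values per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def effect_size_report(
    features: list[FeatureMatrix],
    labels: dict[str, str],
    feature_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature group means/SDs and Cohen's d (positive = ASD > TD).

    Computed on per-participant aggregated values.
    """
    means = participant_feature_means(features)
    groups = pd.Series({p: labels[p] for p in means.index})
    asd = means[groups == ASD]
    td = means[groups == TD]
    cols = feature_subset if feature_subset is not None else list(means.columns)
    rows = []
    for col in cols:
        rows.append({
            "feature": col,
            "mean_asd": asd[col].mean(),
            "sd_asd": asd[col].std(ddof=1),
            "mean_td": td[col].mean(),
            "sd_td": td[col].std(ddof=1),
            "cohens_d": cohens_d(asd[col].to_numpy(), td[col].to_numpy()),
        })
    return pd.DataFrame(rows).set_index("feature")


@dataclass(frozen=True)
class CorrelationRow:
    covariate: str
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def correlate_distance(
    distances: dict[str, float],
    covariate: dict[str, float],
    name: str = "covariate",
) -> CorrelationRow:
    """Pearson and Spearman correlation of boundary distance with a covariate.

    Participants missing either value are dropped; a constant input makes
    the correlation undefined and is reported as NaN.
    """
    pids = sorted(set(distances) & set(covariate))
    pairs = [
        (distances[p], covariate[p])
        for p in pids
        if np.isfinite(distances[p]) and covariate[p] is not None and np.isfinite(covariate[p])
    ]
    if len(pairs) < 3:
        raise DomainError("need at least 3 paired observations")
    x = np.array([d for d, _ in pairs])
    y = np.array([c for _, c in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input for %s; correlation undefined", name)
        return CorrelationRow(name, float("nan"), float("nan"),
                              float("nan"), float("nan"), len(pairs))
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationRow(
        covariate=name,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=len(pairs),
    )


def correlation_report(
    distances: dict[str, float], covariates: pd.DataFrame
) -> pd.DataFrame:
    """Correlate boundary distance with every numeric covariate column."""
    rows = []
    for col in covariates.columns:
        series = covariates[col]
        if not pd.api.types.is_numeric_dtype(series):
            continue
        row = correlate_distance(distances, series.dropna().to_dict(), name=col)
        rows.append(vars(row))
    return pd.DataFrame(rows).set_index("covariate")


def plot_violins(features, labels, feature_subset, path):  # pragma: no cover
    """Violin plots of top features by group (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = participant_feature_means(features)
    groups = pd.Series({p: labels[p] for p in means.index})
    n = len(feature_subset)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 4), squeeze=False)
    for ax, feat in zip(axes[0], feature_subset):
        data = [means.loc[groups == g, feat] for g in (ASD, TD)]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks([1, 2], [ASD, TD])
        ax.set_title(feat, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_distance_scatter(distances, covariate, name, path):  # pragma: no cover
    """Scatter of boundary distance vs one covariate (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pids = sorted(set(distances) & set(covariate))
    x = [covariate[p] for p in pids]
    y = [distances[p] for p in pids]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(name)
    ax.set_ylabel("boundary distance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
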