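"""Sliding-window entropy/variance feature extraction.

Each cleaned timeseries is cut into fixed windows (size 20, shift 10 in
decimated samples by default). For every window and every channel two
summaries are computed: the Shannon entropy of the value histogram (the
"uncertainty" of the movement) and the population variance (its spread),
giving a feature vector of length 2 x n_channels = 124 for the full
schema. Rows per recording vary with its length; columns never do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataio import RawRecording
from .errors import ConfigurationError, DomainError
from .schema import feature_names

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    window_size: int = 20
    window_shift: int = 10
    entropy_bins: int = 10
    entropy_base: str = "nat"  # "nat" or "bit"

    def validate(self) -> None:
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")
        if self.window_shift < 1:
            raise ConfigurationError("window_shift must be >= 1")
        if self.entropy_bins < 2:
            raise ConfigurationError("entropy_bins must be >= 2")
        if self.entropy_base not in ("nat", "bit"):
            raise ConfigurationError("entropy_base must be 'nat' or 'bit'")

    def with_(self, **kwargs) -> "FeatureConfig":
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg


@dataclass
class FeatureMatrix:
    """Windowed features of one recording: n_windows x (2 * n_channels)."""

    participant_id: str
    session: int
    pose_id: int
    vectors: np.ndarray
    feature_names: list[str]

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.vectors, columns=self.feature_names)
        frame.insert(0, "pose_id", self.pose_id)
        frame.insert(0, "session", self.session)
        frame.insert(0, "participant_id", self.participant_id)
        return frame


def window_bounds(T: int, window_size: int, window_shift: int) -> list[tuple[int, int]]:
    """Half-open [start, end) windows; partial end windows are dropped.

    A series shorter than one window contributes no vectors.
    """
    if T < window_size:
        return []
    n = (T - window_size) // window_shift + 1
    return [(k * window_shift, k * window_shift + window_size) for k in range(n)]


def window_variance(values: np.ndarray) -> float:
    """Population variance (divide by the window length)."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise DomainError("window contains missing values; clean the recording first")
    return float(np.var(values))


def window_entropy(values: np.ndarray, bins: int = 10, base: str = "nat") -> float:
    """Shannon entropy of the histogram over equal-width bins on the window's range.

    A constant window (zero range) has entropy 0; 0*log(0) := 0. Shift- and
    scale-invariant by construction (the bins track the window's own range).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    h = float(-(p * np.log(p)).sum())
    if base == "bit":
        h /= np.log(2.0)
    return h


def featurize_recording(
    recording: RawRecording, config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Entropy-then-variance features for every window of every channel.

    Row k = [entropy(ch_1), ..., entropy(ch_C), var(ch_1), ..., var(ch_C)]
    over window k, channels in schema order.
    """
    config = config or FeatureConfig()
    config.validate()
    data = recording.data
    if np.isnan(data).any():
        raise DomainError(
            f"recording {recording.key()} has missing values; clean before featurizing"
        )
    T, C = data.shape
    bounds = window_bounds(T, config.window_size, config.window_shift)
    if not bounds:
        logger.warning(
            "recording %s has %d samples < window %d; contributes no vectors",
            recording.key(), T, config.window_size,
        )
    vectors = np.empty((len(bounds), 2 * C))
    for k, (start, end) in enumerate(bounds):
        win = data[start:end]
        lo = win.min(axis=0)
        hi = win.max(axis=0)
        for c in range(C):
            if hi[c] <= lo[c]:
                vectors[k, c] = 0.0
            else:
                counts, _ = np.histogram(
                    win[:, c], bins=config.entropy_bins, range=(lo[c], hi[c])
                )
                p = counts[counts > 0] / win.shape[0]
                vectors[k, c] = -(p * np.log(p)).sum()
        vectors[k, C:] = win.var(axis=0)
    if config.entropy_base == "bit":
        vectors[:, :C] /= np.log(2.0)
    return FeatureMatrix(
        participant_id=recording.participant_id,
        session=recording.session,
        pose_id=recording.pose_id,
        vectors=vectors,
        feature_names=feature_names(recording.channel_names),
    )


def featurize_dataset(
    recordings: list[RawRecording], config: FeatureConfig | None = None
) -> list[FeatureMatrix]:
    """Featurize a list of cleaned recordings, dropping empty ones."""
    config = config or FeatureConfig()
    out = []
    for rec in recordings:
        fm = featurize_recording(rec, config)
        if fm.n_windows > 0:
            out.append(fm)
    logger.info(
        "featurized %d recordings -> %d matrices, %d vectors total",
        len(recordings), len(out), sum(f.n_windows for f in out),
    )
    return out
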