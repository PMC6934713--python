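"""Four-stage pre-processing of raw recordings.

Stage order: per-channel forward-fill imputation of missing samples;
multilevel Haar discrete-wavelet denoising (the level-L approximation,
amplitude-rescaled so values are dyadic block means); trimming to a
centred window of at most ``trim_max_len`` samples; then a per-pose
variance quality-control pass that fits an exponential distribution to
each channel's variances across files and discards files with any
variance in the far tail (default 1e-7) of that distribution — the
signature of a malfunctioning sensor or an absent participant.

Denoising returns the *decimated* approximation (length ~ T / 2^L), not a
full-length reconstruction; the effective frame rate drops by 2^L and the
downstream sliding window is defined in these decimated samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt

from .dataio import RawRecording
from .errors import CleaningError, ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningConfig:
    wavelet_level: int = 5
    trim_max_len: int = 10_000
    qc_tail: float = 1e-7
    amplitude_preserve: bool = True
    #: Trim in decimated (post-wavelet) samples by default; set False to trim
    #: the raw series before denoising.
    trim_after_wavelet: bool = True

    def validate(self) -> None:
        if self.wavelet_level < 1:
            raise ConfigurationError("wavelet_level must be >= 1")
        if self.trim_max_len < 1:
            raise ConfigurationError("trim_max_len must be >= 1")
        if not 0.0 < self.qc_tail < 1.0:
            raise ConfigurationError("qc_tail must be in (0, 1)")

    def with_(self, **kwargs) -> "CleaningConfig":
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg


@dataclass
class QCReport:
    """Bookkeeping of the variance-QC stage.

    ``thresholds[pose_id]`` is a (channel -> threshold) array, with the
    fitted exponential means alongside; ``discarded`` lists each removed
    file with the channels whose variance exceeded the threshold.
    """

    exp_means: dict[int, np.ndarray] = field(default_factory=dict)
    thresholds: dict[int, np.ndarray] = field(default_factory=dict)
    discarded: list[dict] = field(default_factory=list)
    skipped_poses: list[int] = field(default_factory=list)
    n_input: int = 0

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_input if self.n_input else 0.0

    def discarded_keys(self) -> set[tuple[str, int, int]]:
        return {(d["participant_id"], d["session"], d["pose_id"]) for d in self.discarded}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.discarded)


def forward_fill(series: np.ndarray) -> np.ndarray:
    """Replace each missing value with the nearest preceding valid value.

    Leading missing values are back-filled from the first valid value (the
    forward rule has nothing to propagate there); an all-missing series is
    an error. Idempotent.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise CleaningError("forward_fill expects a 1-D series")
    if np.all(np.isnan(series)):
        raise CleaningError("cannot impute an all-missing channel")
    s = pd.Series(series)
    return s.ffill().bfill().to_numpy()


def forward_fill_matrix(data: np.ndarray) -> np.ndarray:
    """Column-wise forward fill of a T x C matrix."""
    if not np.isnan(data).any():
        return data
    if np.all(np.isnan(data), axis=0).any():
        bad = np.flatnonzero(np.all(np.isnan(data), axis=0))
        raise CleaningError(f"all-missing channels at indices {bad.tolist()}")
    frame = pd.DataFrame(data)
    return frame.ffill().bfill().to_numpy()


def haar_denoise(
    series: np.ndarray, level: int, amplitude_preserve: bool = True
) -> np.ndarray:
    """Level-``level`` Haar approximation of a series (decimated lowpass).

    High-frequency detail is discarded. With ``amplitude_preserve`` the
    coefficients are scaled by 2^(-L/2) so they equal dyadic block means:
    a constant series maps to itself and adding a constant commutes with
    denoising. Boundary rule: symmetric (half-sample) padding, output
    length ceil(T / 2) per level. If T < 2^level the level is reduced to
    floor(log2 T) with a warning.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[0]
    if T < 2:
        raise CleaningError("need at least 2 samples to denoise")
    level = _effective_level(T, level)
    approx = pywt.wavedec(series, "haar", mode="symmetric", level=level, axis=0)[0]
    if amplitude_preserve:
        approx = approx * 2.0 ** (-level / 2.0)
    return approx


def _effective_level(T: int, level: int) -> int:
    max_level = int(math.floor(math.log2(T)))
    if level > max_level:
        logger.warning("series length %d < 2^%d; reducing wavelet level to %d",
                       T, level, max_level)
        return max(1, max_level)
    return level


def trim_middle(series: np.ndarray, max_len: int) -> np.ndarray:
    """Keep the centred window of at most ``max_len`` samples.

    Shorter series pass through unchanged; the window start is
    floor((T - N) / 2) (0-based), discarding the pre- and post-pose motion
    recorded at the ends of each file.
    """
    series = np.asarray(series)
    T = series.shape[0]
    if T <= max_len:
        return series
    start = (T - max_len) // 2
    return series[start : start + max_len]


def clean_recording(recording: RawRecording, config: CleaningConfig) -> RawRecording:
    """Apply imputation, denoising and trimming to one recording."""
    config.validate()
    data = forward_fill_matrix(recording.data)
    if not config.trim_after_wavelet:
        data = trim_middle(data, config.trim_max_len)
    T = data.shape[0]
    if T < 2:
        raise CleaningError(f"recording {recording.key()} too short to denoise")
    level = _effective_level(T, config.wavelet_level)
    approx = pywt.wavedec(data, "haar", mode="symmetric", level=level, axis=0)[0]
    if config.amplitude_preserve:
        approx = approx * 2.0 ** (-level / 2.0)
    if config.trim_after_wavelet:
        approx = trim_middle(approx, config.trim_max_len)
    return RawRecording(
        participant_id=recording.participant_id,
        session=recording.session,
        pose_id=recording.pose_id,
        data=approx,
        channel_names=list(recording.channel_names),
        frame_rate_hz=recording.frame_rate_hz / 2**level,
    )


def variance_qc(
    recordings: list[RawRecording], qc_tail: float = 1e-7
) -> tuple[list[RawRecording], QCReport]:
    """Discard whole files with extreme per-channel variance, per pose.

    For each pose and channel, the variances of that channel across the
    pose's files are modelled as exponential; the maximum-likelihood rate
    is 1/mean, so the upper ``qc_tail`` quantile is mean * ln(1/qc_tail).
    A file is discarded iff any channel's variance exceeds its threshold.
    The fit uses all files of the pose in a single pass (no re-fit after
    discarding). Poses with fewer than two files are skipped with a warning.
    """
    if not 0.0 < qc_tail < 1.0:
        raise ConfigurationError("qc_tail must be in (0, 1)")
    report = QCReport(n_input=len(recordings))
    by_pose: dict[int, list[RawRecording]] = {}
    for rec in recordings:
        by_pose.setdefault(rec.pose_id, []).append(rec)
    kept: list[RawRecording] = []
    log_inv_tail = math.log(1.0 / qc_tail)
    for pose_id in sorted(by_pose):
        group = by_pose[pose_id]
        if len(group) < 2:
            logger.warning("pose %d has %d file(s); variance QC skipped", pose_id, len(group))
            report.skipped_poses.append(pose_id)
            kept.extend(group)
            continue
        variances = np.stack([np.var(rec.data, axis=0) for rec in group])
        means = variances.mean(axis=0)
        thresholds = means * log_inv_tail
        report.exp_means[pose_id] = means
        report.thresholds[pose_id] = thresholds
        for rec, var_row in zip(group, variances):
            over = np.flatnonzero(var_row > thresholds)
            if over.size:
                report.discarded.append(
                    {
                        "participant_id": rec.participant_id,
                        "session": rec.session,
                        "pose_id": rec.pose_id,
                        "offending_dims": over.tolist(),
                        "max_variance": float(var_row[over].max()),
                    }
                )
            else:
                kept.append(rec)
    logger.info(
        "variance QC: discarded %d / %d files (%.1f%%)",
        report.n_discarded, report.n_input, 100.0 * report.discard_fraction,
    )
    return kept, report


def clean_dataset(
    recordings: list[RawRecording], config: CleaningConfig | None = None
) -> tuple[list[RawRecording], QCReport]:
    """Full pipeline: fill -> denoise -> trim per recording, then variance QC."""
    config = config or CleaningConfig()
    config.validate()
    cleaned = [clean_recording(rec, config) for rec in recordings]
    kept, report = variance_qc(cleaned, config.qc_tail)
    logger.info("cleaned %d recordings; %d kept after QC", len(recordings), len(kept))
    return kept, report
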