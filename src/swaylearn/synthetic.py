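"""Synthetic cohort and recording simulator.

The study cohort (two diagnostic groups performing static balance poses in
front of a markerless motion-capture camera while standing on a balance
board) is not publicly released, so this module generates a labelled
surrogate carrying the statistical structure the analysis pipeline assumes:

* a latent motor-atypicality severity per participant, stochastically larger
  in the ASD group, driving both the recordings and the clinical covariates
  (motor percentile down, symptom scores up);
* per-channel signals = slow band-limited drift (postural sway) + first-order
  autoregressive noise whose standard deviation is inflated multiplicatively
  with severity on an "affected" channel subset + independent high-frequency
  sensor jitter;
* an age-dependent noise multiplier, with the ASD curve shifted by a fixed
  developmental delay so that younger typically-developing participants
  resemble older participants on the spectrum;
* rare missing samples, and occasional whole-file corruption (a large
  variance inflation emulating camera/computer malfunction).

All randomness is reproducible: cohort sampling from ``rng_seed``, and each
recording from a stable hash of (rng_seed, participant, session, pose), so
individual files can be regenerated independently and byte-identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .dataio import DatasetManifest, RawRecording, default_filename, write_manifest, write_recording
from .errors import ConfigurationError, DomainError
from .schema import N_CHANNELS

logger = logging.getLogger(__name__)

#: Channel indices carrying the group effect by default: head, both
#: shoulders, both feet (all three axes each) and the two board channels.
DEFAULT_AFFECTED_DIMS: frozenset[int] = frozenset(
    [0, 1, 2]          # head x,y,z
    + [6, 7, 8]        # shoulder_L
    + [9, 10, 11]      # shoulder_R
    + [54, 55, 56]     # foot_L
    + [57, 58, 59]     # foot_R
    + [60, 61]         # board x,y
)


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant: diagnostic label, latent severity and covariates."""

    participant_id: str
    group: str  # "ASD" or "TD"
    age_years: float
    latent_severity: float
    bot2_percentile: float
    srs2_score: float
    rbsr_score: float
    iq: float
    sex: str  # "M" or "F"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model, with the study-shaped defaults.

    ``effect_size_beta`` multiplies the AR-noise SD on affected channels:
    SD = sigma_base * (1 + beta * severity) * age_factor. ``age_slope`` is
    the per-year decrease of the noise multiplier; ``asd_age_delay_years``
    shifts the ASD curve so the group behaves "younger" at equal age.
    """

    n_asd: int = 39
    n_td: int = 23
    sessions: tuple[int, ...] = (2, 3, 4)
    n_poses: int = 10
    frame_rate_hz: float = 30.0
    frames_min: int = 960
    frames_max: int = 1920
    affected_dims: frozenset[int] = DEFAULT_AFFECTED_DIMS
    effect_size_beta: float = 2.0
    age_slope: float = 0.10
    asd_age_delay_years: float = 3.0
    age_reference_years: float = 13.0
    age_min: float = 7.0
    age_max: float = 18.0
    sigma_base: float = 1.0
    ar_coeff: float = 0.95
    drift_amplitude: float = 3.0
    drift_components: int = 3
    drift_max_hz: float = 0.5
    p_missing: float = 1e-5
    jitter_sd: float = 1.0
    p_corrupt_file: float = 0.05
    corrupt_scale: float = 1e4
    # Latent-severity distributions (Gamma, parameterised by mean and shape).
    asd_severity_mean: float = 1.0
    asd_severity_shape: float = 4.0
    td_severity_mean: float = 0.3
    td_severity_shape: float = 2.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_asd < 1:
            raise ConfigurationError("n_asd must be >= 1")
        if self.n_td < 1:
            raise ConfigurationError("n_td must be >= 1")
        if self.n_poses < 1:
            raise ConfigurationError("n_poses must be >= 1")
        if not self.sessions:
            raise ConfigurationError("sessions must be non-empty")
        for name in ("p_missing", "p_corrupt_file"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("sigma_base", "corrupt_scale", "asd_severity_mean",
                     "asd_severity_shape", "td_severity_mean", "td_severity_shape",
                     "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")
        if self.effect_size_beta < 0:
            raise ConfigurationError("effect_size_beta must be >= 0")
        if not 0 < self.frames_min <= self.frames_max:
            raise ConfigurationError("frames_min/frames_max must satisfy 0 < min <= max")
        if not 1 <= self.frames_min:
            raise ConfigurationError("frames_min must be >= 1")
        if not self.affected_dims <= set(range(N_CHANNELS)):
            raise ConfigurationError(f"affected_dims must be a subset of 0..{N_CHANNELS - 1}")
        if not 0 <= self.ar_coeff < 1:
            raise ConfigurationError("ar_coeff must be in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced (validated)."""
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg


def recording_seed(rng_seed: int, participant_id: str, pose_id: int, session: int) -> int:
    """Stable per-recording seed below 2**31, independent of process state."""
    key = f"{rng_seed}|{participant_id}|{session}|{pose_id}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def age_factor(age_years: float, group: str, config: SimulationConfig) -> float:
    """Noise multiplier: decreases with age; ASD shifted by a fixed delay."""
    effective_age = age_years - (config.asd_age_delay_years if group == "ASD" else 0.0)
    return max(0.2, 1.0 + config.age_slope * (config.age_reference_years - effective_age))


def _severity(rng: np.random.Generator, mean: float, shape: float) -> float:
    return float(rng.gamma(shape, mean / shape))


def sample_cohort(config: SimulationConfig) -> list[ParticipantProfile]:
    """Draw the participant cohort: labels, severities and covariates.

    Covariates are monotone functions of latent severity plus noise: the
    standardized motor percentile decreases with severity, the two symptom
    scales increase, all clamped to plausible instrument ranges. IQ and sex
    are drawn from group-specific distributions matching the cohort the
    defaults emulate and are independent of severity.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    profiles: list[ParticipantProfile] = []
    specs = [("ASD", config.n_asd), ("TD", config.n_td)]
    for group, n in specs:
        for i in range(n):
            pid = f"{group.lower()}{i + 1:03d}"
            age = float(rng.uniform(config.age_min, config.age_max))
            if group == "ASD":
                sev = _severity(rng, config.asd_severity_mean, config.asd_severity_shape)
                iq = float(rng.normal(104.0, 15.0))
                sex = "M" if rng.random() < 0.95 else "F"
            else:
                sev = _severity(rng, config.td_severity_mean, config.td_severity_shape)
                iq = float(rng.normal(112.0, 10.0))
                sex = "M" if rng.random() < 0.74 else "F"
            bot2 = float(np.clip(50.0 - 32.0 * sev + rng.normal(0.0, 12.0), 1.0, 99.0))
            srs2 = float(max(0.0, 40.0 + 45.0 * sev + rng.normal(0.0, 6.0)))
            rbsr = float(max(0.0, 2.0 + 25.0 * sev + rng.normal(0.0, 4.0)))
            profiles.append(
                ParticipantProfile(
                    participant_id=pid,
                    group=group,
                    age_years=age,
                    latent_severity=sev,
                    bot2_percentile=bot2,
                    srs2_score=srs2,
                    rbsr_score=rbsr,
                    iq=iq,
                    sex=sex,
                )
            )
    return profiles


def simulate_recording(
    profile: ParticipantProfile,
    pose_id: int,
    session: int,
    config: SimulationConfig,
) -> RawRecording:
    """Simulate one pose performance as a T x 62 matrix.

    Each channel is a sum of three components:

    * slow drift — a mixture of ``drift_components`` sinusoids with random
      frequencies below ``drift_max_hz`` (the posture itself);
    * stationary AR(1) noise with coefficient ``ar_coeff`` whose marginal SD
      is ``sigma_base * (1 + beta*severity*[dim affected]) * age_factor``;
    * independent Gaussian jitter (the high-frequency camera artifact the
      wavelet denoiser targets).

    Cells are then masked missing independently with ``p_missing``.
    """
    config.validate()
    if not 1 <= pose_id <= config.n_poses:
        raise DomainError(f"pose_id {pose_id} out of range 1..{config.n_poses}")
    if session not in config.sessions:
        raise DomainError(f"session {session} not in configured sessions {config.sessions}")
    seed = recording_seed(config.rng_seed, profile.participant_id, pose_id, session)
    rng = np.random.default_rng(seed)
    T = int(rng.integers(config.frames_min, config.frames_max + 1))
    fs = config.frame_rate_hz
    t = np.arange(T) / fs

    # Drift: per-channel sinusoid mixture below drift_max_hz.
    freqs = rng.uniform(0.05, config.drift_max_hz, size=(config.drift_components, N_CHANNELS))
    amps = rng.uniform(0.0, config.drift_amplitude, size=(config.drift_components, N_CHANNELS))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(config.drift_components, N_CHANNELS))
    drift = np.einsum(
        "kc,tkc->tc", amps, np.sin(2.0 * np.pi * t[:, None, None] * freqs[None] + phases[None])
    )

    # AR(1) noise with target stationary SD per channel.
    affected = np.zeros(N_CHANNELS)
    affected[sorted(config.affected_dims)] = 1.0
    target_sd = (
        config.sigma_base
        * (1.0 + config.effect_size_beta * profile.latent_severity * affected)
        * age_factor(profile.age_years, profile.group, config)
    )
    phi = config.ar_coeff
    burn = 200
    eps = rng.standard_normal((T + burn, N_CHANNELS)) * (target_sd * np.sqrt(1.0 - phi**2))
    ar = signal.lfilter([1.0], [1.0, -phi], eps, axis=0)[burn:]

    data = drift + ar
    if config.jitter_sd > 0:
        data = data + rng.normal(0.0, config.jitter_sd, size=(T, N_CHANNELS))
    if config.p_missing > 0:
        mask = rng.random((T, N_CHANNELS)) < config.p_missing
        data[mask] = np.nan
    return RawRecording(
        participant_id=profile.participant_id,
        session=session,
        pose_id=pose_id,
        data=data,
        frame_rate_hz=fs,
    )


def corrupt_recording(
    recording: RawRecording,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[RawRecording, bool]:
    """With probability ``p_corrupt_file`` inflate every channel's variance.

    Deviations from each channel's (NaN-aware) mean are multiplied by
    sqrt(corrupt_scale), so the stored matrix's per-channel variance is
    scaled by exactly ``corrupt_scale``. The flag is the ground truth used
    to score the variance-QC stage.
    """
    if rng.random() >= config.p_corrupt_file:
        return recording, False
    data = recording.data.copy()
    means = np.nanmean(data, axis=0, keepdims=True)
    data = means + np.sqrt(config.corrupt_scale) * (data - means)
    return (
        RawRecording(
            participant_id=recording.participant_id,
            session=recording.session,
            pose_id=recording.pose_id,
            data=data,
            channel_names=list(recording.channel_names),
            frame_rate_hz=recording.frame_rate_hz,
        ),
        True,
    )


def iter_cohort_recordings(config: SimulationConfig, profiles: list[ParticipantProfile]):
    """Yield (profile, recording, corrupted_flag) for every file of the cohort.

    Corruption draws come from a dedicated per-recording stream so that
    whether a file is corrupted does not perturb its underlying signal.
    """
    for profile in profiles:
        for session in config.sessions:
            for pose_id in range(1, config.n_poses + 1):
                rec = simulate_recording(profile, pose_id, session, config)
                corrupt_rng = np.random.default_rng(
                    recording_seed(
                        config.rng_seed + 1_000_003, profile.participant_id, pose_id, session
                    )
                )
                rec, flag = corrupt_recording(rec, config, corrupt_rng)
                yield profile, rec, flag


def generate_dataset(config: SimulationConfig, output_dir: str | Path) -> DatasetManifest:
    """Write one file per (participant, session, pose) plus a manifest.

    Regeneration with the same seed is byte-identical. The manifest carries
    the diagnostic label, covariates and the corruption ground truth.
    """
    import pandas as pd

    config.validate()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    profiles = sample_cohort(config)
    rows = []
    for profile, rec, corrupted in iter_cohort_recordings(config, profiles):
        fname = default_filename(rec.participant_id, rec.session, rec.pose_id)
        write_recording(rec, output_dir / fname)
        rows.append(
            {
                "participant_id": profile.participant_id,
                "group": profile.group,
                "session": rec.session,
                "pose_id": rec.pose_id,
                "path": fname,
                "corrupted": corrupted,
                "age_years": profile.age_years,
                "latent_severity": profile.latent_severity,
                "bot2_percentile": profile.bot2_percentile,
                "srs2_score": profile.srs2_score,
                "rbsr_score": profile.rbsr_score,
                "iq": profile.iq,
                "sex": profile.sex,
            }
        )
    manifest = DatasetManifest(records=pd.DataFrame(rows), root=output_dir)
    write_manifest(manifest, output_dir / "manifest.tsv")
    logger.info("wrote %d recordings to %s", len(rows), output_dir)
    return manifest
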