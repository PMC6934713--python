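"""Reading and writing the delimited timeseries format and dataset manifests.

One recording = one tab-delimited text file: a header row of the 62 channel
names, then one row per frame. Missing cells are written as the literal
token ``NaN``. Round-trips are exact at full float precision (shortest
round-trip repr). Participant/session/pose metadata live in the manifest,
with a default filename pattern ``p<participant>_s<session>_pose<pose>.tsv``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .schema import CHANNELS, N_CHANNELS

logger = logging.getLogger(__name__)

_FILENAME_RE = re.compile(r"^p(?P<pid>.+)_s(?P<session>\d+)_pose(?P<pose>\d+)\.tsv$")

#: Manifest columns describing one recording file.
MANIFEST_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "pose_id",
    "path",
    "corrupted",
]


@dataclass
class RawRecording:
    """One pose performance: a T x C matrix of joint/sway coordinates.

    ``data`` may contain NaN (missing samples). ``channel_names`` defaults to
    the full 62-channel schema but may be a subset (e.g. after an x-y
    projection); file I/O validates against the full schema.
    """

    participant_id: str
    session: int
    pose_id: int
    data: np.ndarray
    channel_names: list[str] = field(default_factory=lambda: list(CHANNELS))
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataFormatError("recording data must be a 2-D matrix")
        if self.data.shape[1] != len(self.channel_names):
            raise DataFormatError(
                f"recording has {self.data.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if self.data.shape[0] < 1:
            raise DataFormatError("recording must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def key(self) -> tuple[str, int, int]:
        return (self.participant_id, self.session, self.pose_id)


def default_filename(participant_id: str, session: int, pose_id: int) -> str:
    return f"p{participant_id}_s{session}_pose{pose_id}.tsv"


def write_recording(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording as tab-delimited text; returns the path written."""
    path = Path(path)
    frame = pd.DataFrame(recording.data, columns=recording.channel_names)
    try:
        # %.17g guarantees bit-exact float round-trips through text.
        frame.to_csv(path, sep="\t", index=False, na_rep="NaN",
                     float_format="%.17g", lineterminator="\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise DataFormatError(f"cannot write recording to {path}: {exc}") from exc
    return path


def read_recording(
    path: str | Path,
    participant_id: str | None = None,
    session: int | None = None,
    pose_id: int | None = None,
    frame_rate_hz: float = 30.0,
) -> RawRecording:
    """Read a recording file, validating the 62-channel schema.

    Metadata not supplied explicitly is parsed from the default filename
    pattern; files named otherwise must come with explicit metadata.
    """
    path = Path(path)
    if participant_id is None or session is None or pose_id is None:
        m = _FILENAME_RE.match(path.name)
        if m is None:
            raise DataFormatError(
                f"{path}: metadata not supplied and filename does not match "
                "the p<participant>_s<session>_pose<pose>.tsv pattern"
            )
        participant_id = participant_id or m.group("pid")
        session = session if session is not None else int(m.group("session"))
        pose_id = pose_id if pose_id is not None else int(m.group("pose"))
    try:
        frame = pd.read_csv(path, sep="\t", na_values=["NaN"], keep_default_na=False,
                            float_precision="round_trip")
    except FileNotFoundError:
        raise
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"{path}: cannot parse timeseries file: {exc}") from exc
    if list(frame.columns) != list(CHANNELS):
        raise DataFormatError(
            f"{path}: expected the {N_CHANNELS} canonical channel columns, "
            f"found {len(frame.columns)}"
        )
    if len(frame) < 1:
        raise DataFormatError(f"{path}: empty data section (need at least one frame)")
    try:
        data = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: unparseable numeric cell: {exc}") from exc
    return RawRecording(
        participant_id=str(participant_id),
        session=int(session),
        pose_id=int(pose_id),
        data=data,
        frame_rate_hz=frame_rate_hz,
    )


@dataclass
class DatasetManifest:
    """Tabular index of a dataset: one row per recording file.

    Carries diagnostic labels, covariates and the simulator's corruption
    ground truth alongside file paths. (participant, session, pose) keys are
    unique and every path is resolvable relative to ``root``.
    """

    records: pd.DataFrame
    root: Path | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataFormatError(f"manifest missing columns: {missing}")
        keys = self.records[["participant_id", "session", "pose_id"]]
        if keys.duplicated().any():
            raise DataFormatError("manifest has duplicate (participant, session, pose) keys")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> dict[str, str]:
        """participant_id -> group label."""
        sub = self.records.drop_duplicates("participant_id")
        return dict(zip(sub["participant_id"].astype(str), sub["group"]))

    def covariates(self) -> pd.DataFrame:
        """One row per participant with every non-file column."""
        drop = ["session", "pose_id", "path", "corrupted"]
        cols = [c for c in self.records.columns if c not in drop]
        return (
            self.records[cols]
            .drop_duplicates("participant_id")
            .set_index("participant_id")
        )

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.records.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    records = pd.read_csv(path, sep="\t")
    records["participant_id"] = records["participant_id"].astype(str)
    return DatasetManifest(records=records, root=path.parent)


def load_dataset(
    manifest: DatasetManifest, sessions: set[int] | None = None
) -> list[RawRecording]:
    """Load recordings, restricted to the given sessions (None = all).

    The study analyses sessions 2-4 only; the default CLI configuration
    applies that filter. Missing files raise with the full offending list.
    """
    rows = manifest.records
    if sessions is not None:
        rows = rows[rows["session"].isin(list(sessions))]
    missing = [str(p) for p in rows["path"] if not manifest.resolve(p).exists()]
    if missing:
        raise DataFormatError("manifest refers to missing files: " + ", ".join(missing))
    recordings = [
        read_recording(
            manifest.resolve(row.path),
            participant_id=str(row.participant_id),
            session=int(row.session),
            pose_id=int(row.pose_id),
        )
        for row in rows.itertuples()
    ]
    logger.info(
        "loaded %d recordings (sessions=%s)", len(recordings),
        "all" if sessions is None else sorted(sessions),
    )
    return recordings
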