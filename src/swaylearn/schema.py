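"""Canonical channel and feature naming for the 62-dimensional recordings.

A recording holds, per frame, the 3-D positions of 20 markerless skeleton
joints followed by the 2-D centre-of-pressure position from the balance
board: 20 x 3 + 2 = 62 channels. The joint order is fixed; every reader,
writer and feature report relies on it.
"""

from __future__ import annotations

JOINTS: tuple[str, ...] = (
    "head",
    "shoulder_center",
    "shoulder_L",
    "shoulder_R",
    "elbow_L",
    "elbow_R",
    "wrist_L",
    "wrist_R",
    "hand_L",
    "hand_R",
    "spine",
    "hip_center",
    "hip_L",
    "hip_R",
    "knee_L",
    "knee_R",
    "ankle_L",
    "ankle_R",
    "foot_L",
    "foot_R",
)

AXES: tuple[str, ...] = ("x", "y", "z")

#: The 62 canonical channel names: "head:x", ..., "foot_R:z", "board:x", "board:y".
CHANNELS: tuple[str, ...] = tuple(
    f"{joint}:{axis}" for joint in JOINTS for axis in AXES
) + ("board:x", "board:y")

N_CHANNELS: int = len(CHANNELS)  # 62

#: Indices of the two balance-board (postural sway) channels.
BOARD_DIMS: tuple[int, int] = (60, 61)


def feature_names(channels: tuple[str, ...] | list[str] = CHANNELS) -> list[str]:
    """Ordered feature names: entropy of every channel, then variance.

    For the full 62-channel schema this yields the 124-name vocabulary used
    in importance reports (e.g. ``entropy:shoulder_R:y``, ``variance:board:x``).
    """
    chans = list(channels)
    return [f"entropy:{c}" for c in chans] + [f"variance:{c}" for c in chans]


def xy_channels() -> list[str]:
    """Channel subset with every joint z-axis dropped (42 channels).

    The board channels are two-dimensional already and are retained.
    """
    return [c for c in CHANNELS if not c.endswith(":z")]


def joint_dims(joint: str) -> list[int]:
    """Indices of the three coordinate channels of one joint."""
    if joint not in JOINTS:
        raise KeyError(f"unknown joint {joint!r}")
    j = JOINTS.index(joint)
    return [3 * j, 3 * j + 1, 3 * j + 2]
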