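"""Core domain types for the posture-monitoring pipeline.

A worker wears five inertial measurement units (IMUs) — on the head, chest
centre, upper arm, thigh and calf. Each unit streams a triaxial accelerometer
(in g) and a triaxial gyroscope (in degrees/second), giving a fixed 30-channel
layout per session. Recognition operates at a one-second cadence: the pipeline
turns raw channel matrices into per-second posture labels, and every downstream
risk statistic is computed from those label streams.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class SensorPlacement(enum.Enum):
    """Body location of one IMU. Exactly five placements are supported."""

    HEAD = "HEAD"
    CHEST = "CHEST"
    UPPER_ARM = "UPPER_ARM"
    THIGH = "THIGH"
    CALF = "CALF"


# Stable placement order used everywhere a channel matrix is built.
PLACEMENT_ORDER: tuple[SensorPlacement, ...] = (
    SensorPlacement.HEAD,
    SensorPlacement.CHEST,
    SensorPlacement.UPPER_ARM,
    SensorPlacement.THIGH,
    SensorPlacement.CALF,
)


class Modality(enum.Enum):
    ACCEL = "ACCEL"
    GYRO = "GYRO"


class Axis(enum.Enum):
    X = "X"
    Y = "Y"
    Z = "Z"


@dataclass(frozen=True, order=False)
class ChannelId:
    """One of the 30 session channels: (placement, modality, axis).

    The total ordering — placement (HEAD, CHEST, UPPER_ARM, THIGH, CALF),
    then modality (ACCEL before GYRO), then axis (X, Y, Z) — fixes the column
    layout of every session matrix and is identical across runs and platforms.
    """

    placement: SensorPlacement
    modality: Modality
    axis: Axis

    def __str__(self) -> str:
        return f"{self.placement.value}.{self.modality.value}.{self.axis.value}"

    @property
    def column(self) -> int:
        """Column index of this channel in a session matrix."""
        p = PLACEMENT_ORDER.index(self.placement)
        m = 0 if self.modality is Modality.ACCEL else 1
        a = (Axis.X, Axis.Y, Axis.Z).index(self.axis)
        return p * 6 + m * 3 + a


def all_channels() -> list[ChannelId]:
    """The 30 channels in canonical column order."""
    out = []
    for p in PLACEMENT_ORDER:
        for m in (Modality.ACCEL, Modality.GYRO):
            for a in (Axis.X, Axis.Y, Axis.Z):
                out.append(ChannelId(p, m, a))
    return out


N_CHANNELS = 30


class PostureLabel(enum.Enum):
    """The seven working-posture classes plus an internal gap marker.

    BT bending, KN kneeling, MO climbing (ladder motion), SQ squatting,
    ST standing with minor movement, WK walking, WO overhead work.
    UNKNOWN marks unassessable seconds (sensor gaps) and never contributes
    to risk statistics.
    """

    BT = "BT"
    KN = "KN"
    MO = "MO"
    SQ = "SQ"
    ST = "ST"
    WK = "WK"
    WO = "WO"
    UNKNOWN = "UNKNOWN"


#: The seven real posture codes in the fixed alphabetical label order used by
#: classifiers (argmax ties break toward the lowest index here).
LABEL_ORDER: tuple[PostureLabel, ...] = (
    PostureLabel.BT,
    PostureLabel.KN,
    PostureLabel.MO,
    PostureLabel.SQ,
    PostureLabel.ST,
    PostureLabel.WK,
    PostureLabel.WO,
)

#: Postures counted as awkward (injury-prone) by default.
DEFAULT_AWKWARD_SET = frozenset(
    {PostureLabel.BT, PostureLabel.KN, PostureLabel.SQ, PostureLabel.WO}
)


class TimelineSource(enum.Enum):
    GROUND_TRUTH = "GROUND_TRUTH"
    PREDICTED = "PREDICTED"


@dataclass
class ImuRecording:
    """Raw samples from one sensor placement.

    ``accel`` is (n, 3) in g, ``gyro`` is (n, 3) in deg/s, ``timestamps``
    is (n,) milliseconds since the Unix epoch and strictly increasing.
    ``rate`` is the nominal sampling rate in Hz.
    """

    placement: SensorPlacement
    start_epoch: int  # ms
    rate: int  # Hz
    accel: np.ndarray
    gyro: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel and gyro must both be (n, 3)")
        if len(self.timestamps) != len(self.accel):
            raise ValueError("one timestamp per sample required")
        if len(self.timestamps) == 0:
            raise ValueError("recording must contain at least one sample")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise IntegrityError(f"timestamps not strictly increasing at row {bad}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration_ms(self) -> int:
        return int(self.timestamps[-1] - self.timestamps[0])


@dataclass
class SessionData:
    """Time-aligned 30-channel matrix for one worker session.

    ``matrix`` is (T, 30) ordered by the canonical channel order;
    ``gap_mask`` flags samples that were zero-filled or interpolated across
    gaps and must not feed recognition.
    """

    worker_id: str
    trade: str
    start_epoch: int  # ms
    rate: int  # Hz
    matrix: np.ndarray
    gap_mask: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_CHANNELS:
            raise ValueError(f"session matrix must have exactly {N_CHANNELS} columns")
        if self.matrix.shape[0] < 1:
            raise ValueError("session must contain at least one sample")
        if self.gap_mask.shape != (self.matrix.shape[0],):
            raise ValueError("gap_mask must have one flag per sample")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class PostureTimeline:
    """Per-second posture labels for one worker, starting at ``start_epoch``.

    This is both the recognition output and the assessment input: element i
    is the posture held during second i of the session.
    """

    worker_id: str
    trade: str
    start_epoch: int  # ms
    labels: list[PostureLabel]
    source: TimelineSource = TimelineSource.GROUND_TRUTH

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) < 1:
            raise ValueError("timeline must contain at least one second")
        for lab in self.labels:
            if not isinstance(lab, PostureLabel):
                raise TypeError(f"not a PostureLabel: {lab!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def start_epoch_s(self) -> int:
        return self.start_epoch // 1000


class FormatError(ValueError):
    """A file does not conform to the expected CSV layout."""


class IntegrityError(ValueError):
    """Data violates an internal consistency requirement."""


class AlignmentError(ValueError):
    """Recordings cannot be placed on a common clock."""
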