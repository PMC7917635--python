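"""Reading, writing and time-aligning sensor CSV files and posture timelines.

Sensor files follow the one-file-per-placement shape of commodity IMU logger
exports: a header ``epoch_ms,ax,ay,az,gx,gy,gz`` and one row per sample, with
accelerometer columns in g and gyroscope columns in deg/s. Timelines are CSV
with columns ``epoch_s,label``, one row per second.

Alignment places every placement's channels on a common grid covering the
temporal intersection of the recordings, by per-channel linear interpolation.
Placements absent from a session are zero-filled and flagged in the gap mask,
as are stretches where a recording has no sample within two grid steps.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import (
    AlignmentError,
    FormatError,
    ImuRecording,
    IntegrityError,
    N_CHANNELS,
    PLACEMENT_ORDER,
    PostureLabel,
    PostureTimeline,
    SensorPlacement,
    SessionData,
    TimelineSource,
)

SENSOR_COLUMNS = ["epoch_ms", "ax", "ay", "az", "gx", "gy", "gz"]
TIMELINE_COLUMNS = ["epoch_s", "label"]


def infer_rate(timestamps_ms: np.ndarray) -> int:
    """Nominal rate in Hz: reciprocal of the median inter-sample interval,
    rounded to the nearest integer (minimum 1)."""
    if len(timestamps_ms) < 2:
        return 1
    dt = np.median(np.diff(timestamps_ms)) / 1000.0
    return max(1, int(round(1.0 / dt)))


def read_sensor_csv(path: str | os.PathLike, placement: SensorPlacement) -> ImuRecording:
    """Parse one placement's sensor CSV into an :class:`ImuRecording`.

    Raises :class:`FormatError` naming any missing column and
    :class:`IntegrityError` (with the first offending row index) when the
    timestamp column is not strictly increasing.
    """
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    ts = df["epoch_ms"].to_numpy(dtype=np.int64)
    diffs = np.diff(ts)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise IntegrityError(f"{path}: timestamps not strictly increasing at row {row}")
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    return ImuRecording(
        placement=placement,
        start_epoch=int(ts[0]),
        rate=infer_rate(ts),
        accel=accel,
        gyro=gyro,
        timestamps=ts,
    )


def write_sensor_csv(rec: ImuRecording, path: str | os.PathLike) -> None:
    """Write a recording as a sensor CSV re-readable by :func:`read_sensor_csv`."""
    if rec.n_samples == 0:
        raise ValueError("refusing to write a recording with zero samples")
    df = pd.DataFrame(
        {
            "epoch_ms": rec.timestamps,
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
            "gx": rec.gyro[:, 0],
            "gy": rec.gyro[:, 1],
            "gz": rec.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def align_session(
    recordings: Iterable[ImuRecording],
    target_rate: int = 25,
    worker_id: str = "",
    trade: str = "",
) -> SessionData:
    """Resample recordings onto a common grid and stack them as a session.

    The grid runs from the latest recording start to the earliest end at
    ``target_rate``. Channels are linearly interpolated; placements without a
    recording are zero-filled and masked, and grid points farther than two
    grid steps from any source sample are masked as gaps.
    """
    recs: dict[SensorPlacement, ImuRecording] = {}
    for r in recordings:
        if r.placement in recs:
            raise ValueError(f"duplicate placement {r.placement.value}")
        recs[r.placement] = r
    if not recs:
        raise ValueError("at least one recording required")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")

    t0 = max(int(r.timestamps[0]) for r in recs.values())
    t1 = min(int(r.timestamps[-1]) for r in recs.values())
    if t1 - t0 < 1000:
        intervals = {
            r.placement.value: (int(r.timestamps[0]), int(r.timestamps[-1]))
            for r in recs.values()
        }
        raise AlignmentError(
            f"recordings overlap for less than 1 s: intervals (ms) {intervals}"
        )

    step_ms = 1000.0 / target_rate
    n = int(np.floor((t1 - t0) / step_ms)) + 1
    grid = t0 + np.arange(n) * step_ms

    matrix = np.zeros((n, N_CHANNELS))
    gap = np.zeros(n, dtype=bool)
    max_gap_ms = 2 * step_ms

    for pi, placement in enumerate(PLACEMENT_ORDER):
        base = pi * 6
        rec = recs.get(placement)
        if rec is None:
            gap[:] = True  # absent placement taints every sample
            continue
        ts = rec.timestamps.astype(float)
        for ci in range(3):
            matrix[:, base + ci] = np.interp(grid, ts, rec.accel[:, ci])
            matrix[:, base + 3 + ci] = np.interp(grid, ts, rec.gyro[:, ci])
        # flag grid points inside source gaps longer than two grid steps
        idx = np.searchsorted(ts, grid)
        idx = np.clip(idx, 1, len(ts) - 1)
        local_gap = ts[idx] - ts[idx - 1]
        gap |= local_gap > max_gap_ms

    return SessionData(
        worker_id=worker_id,
        trade=trade,
        start_epoch=int(t0),
        rate=int(target_rate),
        matrix=matrix,
        gap_mask=gap,
    )


def write_timeline(tl: PostureTimeline, path: str | os.PathLike) -> None:
    """Serialize a timeline as ``epoch_s,label`` CSV, one row per second."""
    start_s = tl.start_epoch // 1000
    df = pd.DataFrame(
        {
            "epoch_s": start_s + np.arange(len(tl.labels)),
            "label": [lab.value for lab in tl.labels],
        }
    )
    df.to_csv(path, index=False)


def read_timeline(
    path: str | os.PathLike,
    worker_id: str = "",
    trade: str = "",
    source: TimelineSource = TimelineSource.GROUND_TRUTH,
) -> PostureTimeline:
    """Parse a timeline CSV. Unknown label strings raise :class:`FormatError`."""
    df = pd.read_csv(path)
    missing = [c for c in TIMELINE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    labels = []
    for raw in df["label"]:
        try:
            labels.append(PostureLabel(str(raw)))
        except ValueError:
            raise FormatError(f"{path}: unknown posture label {raw!r}") from None
    epochs = df["epoch_s"].to_numpy(dtype=np.int64)
    if len(epochs) > 1 and np.any(np.diff(epochs) != 1):
        row = int(np.argmax(np.diff(epochs) != 1)) + 1
        raise IntegrityError(f"{path}: seconds not contiguous at row {row}")
    return PostureTimeline(
        worker_id=worker_id,
        trade=trade,
        start_epoch=int(epochs[0]) * 1000,
        labels=labels,
        source=source,
    )


def write_session_meta(session: SessionData, path: str | os.PathLike) -> None:
    """Key-value sidecar with session metadata."""
    with open(path, "w") as fh:
        fh.write(f"worker_id={session.worker_id}\n")
        fh.write(f"trade={session.trade}\n")
        fh.write(f"rate={session.rate}\n")
        fh.write(f"start_epoch={session.start_epoch}\n")


def read_session_meta(path: str | os.PathLike) -> Mapping[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                meta[k] = v
    return meta
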