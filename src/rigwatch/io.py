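"""Reading, writing and labeling of accelerometer streams and time-study logs.

Accelerometer samples are tri-axial, in thousandths of standard gravity
(mgn), nominally at 25 Hz.  Time-study logs are ordered, non-overlapping
activity episodes recorded by a human observer.  Labeling attaches each
sample to the episode whose half-open interval ``[start, stop)`` contains
its timestamp; samples outside every episode get the ``UNLABELED``
sentinel.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

UNLABELED = "UNLABELED"

CHOKER_SETTER = "choker_setter"
CHASER = "chaser"

#: Work-cycle elements per worker type, in within-cycle order.
ACTIVITIES = {
    CHOKER_SETTER: ("travel_to_log", "set_choker", "travel_away", "clear"),
    CHASER: ("travel_to_log", "unhook", "travel_away", "clear"),
}

ACCEL_COLUMNS = ("timestamp", "ax_mgn", "ay_mgn", "az_mgn")
TIME_STUDY_COLUMNS = ("activity", "start", "stop")


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class CorruptionError(ValueError):
    """Data violates a structural invariant (e.g. duplicate timestamps)."""


class EmptyInputError(ValueError):
    """A file contains no data rows."""


def _to_epoch_ms(values) -> np.ndarray:
    """Normalize a timestamp column (epoch ms or ISO-8601) to int64 ms."""
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.number):
        return np.asarray(np.round(arr), dtype=np.int64)
    parsed = pd.to_datetime(pd.Series(arr), format="ISO8601", utc=True)
    return (parsed.astype("int64") // 1_000_000).to_numpy()


@dataclasses.dataclass
class AccelStream:
    """Timestamped tri-axial acceleration samples (mgn) at a nominal rate.

    Parameters
    ----------
    session_id : str
        Identifier of the recording session.
    rate_hz : float
        Nominal sampling rate; the watch default is 25 Hz.
    t : ndarray of int64
        Sample timestamps, epoch milliseconds, strictly increasing.
    ax, ay, az : ndarray of float
        Per-axis acceleration in mgn.
    """

    session_id: str
    rate_hz: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        for name in ("ax", "ay", "az"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("axis arrays must match timestamp length")
        if n == 0:
            raise EmptyInputError("stream contains no samples")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise CorruptionError(
                    f"timestamps not strictly increasing at index {i + 1}"
                )
            nominal = 1000.0 / self.rate_hz
            med = float(np.median(dt))
            if abs(med - nominal) > 0.2 * nominal:
                raise CorruptionError(
                    f"median inter-sample gap {med:.1f} ms deviates more than "
                    f"20% from nominal {nominal:.1f} ms"
                )
        for name in ("ax", "ay", "az"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise CorruptionError(f"non-finite values in {name}")


@dataclasses.dataclass
class Episode:
    activity: str
    start: int  # epoch ms, inclusive
    stop: int  # epoch ms, exclusive


@dataclasses.dataclass
class TimeStudyLog:
    """Ordered, non-overlapping activity episodes for one worker session."""

    worker_type: str
    episodes: list[Episode]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.worker_type not in ACTIVITIES:
            raise ValueError(f"unknown worker_type {self.worker_type!r}")
        valid = set(ACTIVITIES[self.worker_type])
        self.episodes = sorted(self.episodes, key=lambda e: e.start)
        prev: Episode | None = None
        for ep in self.episodes:
            if ep.activity not in valid:
                raise FormatError(
                    f"unknown activity {ep.activity!r} for {self.worker_type}"
                )
            if ep.start >= ep.stop:
                raise FormatError(
                    f"episode {ep.activity!r} has start {ep.start} >= stop {ep.stop}"
                )
            if prev is not None and ep.start < prev.stop:
                raise FormatError(
                    f"episodes overlap: ({prev.activity!r}, {prev.start}, {prev.stop}) "
                    f"and ({ep.activity!r}, {ep.start}, {ep.stop})"
                )
            prev = ep

    def __len__(self) -> int:
        return len(self.episodes)


@dataclasses.dataclass
class LabeledMagnitudeSeries:
    """Filtered acceleration-magnitude samples, each carrying an activity label."""

    session_id: str
    rate_hz: float
    t: np.ndarray
    amag: np.ndarray
    labels: np.ndarray  # dtype object/str; UNLABELED where no episode applies

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.amag = np.asarray(self.amag, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.t) == len(self.amag) == len(self.labels)):
            raise ValueError("t, amag and labels must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise CorruptionError("timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def read_accel_csv(path, session_id: str | None = None, rate_hz: float = 25.0) -> AccelStream:
    """Read an accelerometer CSV (``timestamp,ax_mgn,ay_mgn,az_mgn``).

    Timestamps may be epoch milliseconds or ISO-8601; they are normalized
    to integer epoch ms and the rows sorted by timestamp.
    """
    df = pd.read_csv(path)
    for col in ACCEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        raise EmptyInputError(f"no samples in {path}")
    t = _to_epoch_ms(df["timestamp"].to_numpy())
    order = np.argsort(t, kind="stable")
    return AccelStream(
        session_id=session_id or str(path),
        rate_hz=rate_hz,
        t=t[order],
        ax=df["ax_mgn"].to_numpy()[order],
        ay=df["ay_mgn"].to_numpy()[order],
        az=df["az_mgn"].to_numpy()[order],
    )


def write_accel_csv(stream: AccelStream, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": stream.t,
            "ax_mgn": stream.ax,
            "ay_mgn": stream.ay,
            "az_mgn": stream.az,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_time_study_csv(path, worker_type: str) -> TimeStudyLog:
    """Read a time-study CSV (``activity,start,stop``) for one worker type."""
    df = pd.read_csv(path)
    for col in TIME_STUDY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        raise EmptyInputError(f"no episodes in {path}")
    starts = _to_epoch_ms(df["start"].to_numpy())
    stops = _to_epoch_ms(df["stop"].to_numpy())
    episodes = [
        Episode(str(a), int(s), int(e))
        for a, s, e in zip(df["activity"], starts, stops)
    ]
    return TimeStudyLog(worker_type=worker_type, episodes=episodes)


def write_time_study_csv(log: TimeStudyLog, path) -> None:
    df = pd.DataFrame(
        {
            "activity": [e.activity for e in log.episodes],
            "start": [e.start for e in log.episodes],
            "stop": [e.stop for e in log.episodes],
        }
    )
    df.to_csv(path, index=False)


def label_timestamps(t: np.ndarray, log: TimeStudyLog) -> np.ndarray:
    """Label each timestamp by the episode whose ``[start, stop)`` contains it."""
    t = np.asarray(t, dtype=np.int64)
    labels = np.full(len(t), UNLABELED, dtype=object)
    starts = np.array([e.start for e in log.episodes], dtype=np.int64)
    stops = np.array([e.stop for e in log.episodes], dtype=np.int64)
    # episodes are sorted and non-overlapping: searchsorted finds the last
    # episode starting at or before each t; half-open on the right.
    idx = np.searchsorted(starts, t, side="right") - 1
    valid = idx >= 0
    inside = np.zeros(len(t), dtype=bool)
    inside[valid] = t[valid] < stops[idx[valid]]
    acts = np.array([e.activity for e in log.episodes], dtype=object)
    labels[inside] = acts[idx[inside]]
    return labels


def label_samples(
    t: np.ndarray,
    amag: np.ndarray,
    log: TimeStudyLog,
    session_id: str = "",
    rate_hz: float = 25.0,
) -> LabeledMagnitudeSeries:
    """Attach activity labels to a magnitude series via a time-study log.

    A sample at the exact boundary between consecutive episodes belongs to
    the episode that starts there; sample count is unchanged.
    """
    return LabeledMagnitudeSeries(
        session_id=session_id,
        rate_hz=rate_hz,
        t=t,
        amag=amag,
        labels=label_timestamps(t, log),
    )


def write_magnitude_csv(series: LabeledMagnitudeSeries, path) -> None:
    pd.DataFrame(
        {"timestamp": series.t, "amag_mgn": series.amag, "label": series.labels}
    ).to_csv(path, index=False, float_format="%.6f")
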