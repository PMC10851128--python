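"""Sensor streams and packet-log I/O.

A :class:`LabeledStream` holds a sequence of sensor packets as a pandas
DataFrame — one row per packet with the device timestamp (seconds since
session start), thigh-inclination angle (degrees from vertical), triaxial
accelerometer (g), gyroscope (deg/s) and magnetometer (µT) readings, and
battery voltage — plus, when known, a per-packet ground-truth activity label
and variation tag.

Packet logs are written as CSV with the raw-logger column schema
(``date, time, angle, accelX … magZ, battery_voltage``); ground-truth labels
travel in a sidecar CSV (``timestamp, label, variation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Numeric sensor channels, in storage order.
CHANNEL_COLUMNS: tuple[str, ...] = (
    "angle",
    "accel_x",
    "accel_y",
    "accel_z",
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "mag_x",
    "mag_y",
    "mag_z",
    "battery_voltage",
)

#: Raw packet-log CSV header (logger naming convention).
LOG_COLUMNS: tuple[str, ...] = (
    "date",
    "time",
    "angle",
    "accelX",
    "accelY",
    "accelZ",
    "gyroX",
    "gyroY",
    "gyroZ",
    "magX",
    "magY",
    "magZ",
    "battery_voltage",
)

_LOG_TO_CHANNEL = {
    "angle": "angle",
    "accelX": "accel_x",
    "accelY": "accel_y",
    "accelZ": "accel_z",
    "gyroX": "gyro_x",
    "gyroY": "gyro_y",
    "gyroZ": "gyro_z",
    "magX": "mag_x",
    "magY": "mag_y",
    "magZ": "mag_z",
    "battery_voltage": "battery_voltage",
}

DEFAULT_SESSION_DATE = "2024-01-01"
DEFAULT_SESSION_TIME = "09:00:00"


@dataclass
class LabeledStream:
    """Regularly (or, after packet loss, irregularly) sampled packet sequence.

    ``data`` columns: ``timestamp`` plus :data:`CHANNEL_COLUMNS`, and
    optionally ``label`` / ``variation`` when ground truth is attached.
    """

    data: pd.DataFrame
    sampling_rate: float = 25.0
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        if "timestamp" not in self.data.columns:
            raise ValueError("stream data must have a 'timestamp' column")
        ts = self.data["timestamp"].to_numpy()
        if len(ts) > 1 and np.any(np.diff(ts) <= 0):
            bad = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at row {bad}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_labels(self) -> bool:
        return "label" in self.data.columns

    @property
    def timestamps(self) -> np.ndarray:
        return self.data["timestamp"].to_numpy()

    @property
    def labels(self) -> pd.Series:
        if not self.has_labels:
            raise AttributeError("stream carries no ground-truth labels")
        return self.data["label"]

    @property
    def duration(self) -> float:
        ts = self.timestamps
        return float(ts[-1] - ts[0]) + 1.0 / self.sampling_rate if len(ts) else 0.0

    def channels(self, names: tuple[str, ...] | list[str] = CHANNEL_COLUMNS) -> np.ndarray:
        """Channel matrix of shape (n_packets, n_channels)."""
        return self.data[list(names)].to_numpy(dtype=float)

    def is_regular(self, rtol: float = 1e-6) -> bool:
        """True when consecutive timestamps differ by one sample period."""
        ts = self.timestamps
        if len(ts) < 2:
            return True
        period = 1.0 / self.sampling_rate
        return bool(np.allclose(np.diff(ts), period, rtol=rtol, atol=period * 1e-6))

    def with_data(self, data: pd.DataFrame) -> "LabeledStream":
        return replace(self, data=data.reset_index(drop=True))


def _format_clock(seconds: np.ndarray, start: str) -> tuple[np.ndarray, np.ndarray]:
    """Split session-relative seconds into date and wall-clock strings."""
    base = pd.Timestamp(f"{DEFAULT_SESSION_DATE} {start}")
    # round to whole milliseconds: exact at 25 Hz (40 ms) spacing
    ms = np.rint(np.asarray(seconds, dtype=float) * 1000.0).astype(np.int64)
    stamps = base + pd.to_timedelta(ms, unit="ms")
    return stamps.strftime("%Y-%m-%d").to_numpy(), stamps.strftime("%H:%M:%S.%f").to_numpy()


def write_packet_log(
    stream: LabeledStream,
    path: str | Path,
    labels_path: str | Path | None = None,
    session_start: str = DEFAULT_SESSION_TIME,
) -> None:
    """Write a raw packet-log CSV, and optionally a label sidecar CSV."""
    dates, times = _format_clock(stream.timestamps, session_start)
    out = pd.DataFrame({"date": dates, "time": times})
    for log_col, chan in _LOG_TO_CHANNEL.items():
        out[log_col] = stream.data[chan].to_numpy()
    out.to_csv(path, index=False, columns=list(LOG_COLUMNS))
    if labels_path is not None:
        if not stream.has_labels:
            raise ValueError("stream has no labels to write")
        side = pd.DataFrame(
            {
                "timestamp": stream.timestamps,
                "label": stream.data["label"].to_numpy(),
                "variation": stream.data.get(
                    "variation", pd.Series([""] * len(stream))
                ).to_numpy(),
            }
        )
        side.to_csv(labels_path, index=False)


def read_label_sidecar(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth sidecar CSV (timestamp, label, variation)."""
    df = pd.read_csv(path, dtype={"label": str, "variation": str})
    missing = {"timestamp", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label sidecar missing columns: {sorted(missing)}")
    return df


def attach_labels(stream: LabeledStream, sidecar: pd.DataFrame) -> LabeledStream:
    """Attach sidecar labels to a stream by nearest timestamp."""
    ts = stream.timestamps
    idx = np.searchsorted(sidecar["timestamp"].to_numpy(), ts, side="left")
    idx = np.clip(idx, 0, len(sidecar) - 1)
    data = stream.data.copy()
    data["label"] = sidecar["label"].to_numpy()[idx]
    if "variation" in sidecar.columns:
        data["variation"] = sidecar["variation"].to_numpy()[idx]
    return stream.with_data(data)
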