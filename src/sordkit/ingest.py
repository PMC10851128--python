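"""Packet-log ingestion and packet-loss repair.

Raw logs carry the sender-side device timestamp of every packet, so dropped
packets appear as enlarged timestamp deltas.  For a nominal sampling rate
``r`` the number of samples missing between consecutive packets is

    missing = round(ΔT × r) − 1   (floored at 0)

Rounding, rather than truncation, absorbs device-clock jitter up to half a
sample period.  Each missing slot is filled with the **average of the two
surviving neighbors** of the gap — a constant fill, the same value for every
slot in a multi-sample gap (linear interpolation is available behind a flag).
Gaps at a stream boundary have only one neighbor and take its value.

Outlier policy: samples with any channel outside physical bounds are treated
as missing and refilled by the same neighbor-average rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stream import CHANNEL_COLUMNS, LOG_COLUMNS, _LOG_TO_CHANNEL, LabeledStream

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The input file does not match the expected packet-log schema."""


class OrderingError(ValueError):
    """Packet timestamps are not strictly increasing."""


class DataQualityError(ValueError):
    """The stream is too degraded to repair."""


@dataclass(frozen=True)
class GapReport:
    """Packet-loss summary: one entry per detected gap.

    Each gap is ``(index_after_which, delta_t_seconds, missing_count)`` where
    the index refers to the surviving packet immediately before the gap.
    """

    gaps: tuple[tuple[int, float, int], ...]
    total_missing: int
    sampling_rate: float

    def __post_init__(self) -> None:
        if any(m < 1 for _, _, m in self.gaps):
            raise ValueError("every reported gap must have missing_count >= 1")
        if self.total_missing != sum(m for _, _, m in self.gaps):
            raise ValueError("total_missing inconsistent with gap list")

    def to_json_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "total_missing": self.total_missing,
            "gaps": [
                {"after_index": i, "delta_t_s": dt, "missing": m}
                for i, dt, m in self.gaps
            ],
        }


def read_packet_log(
    path: str | Path, sampling_rate: float = 25.0
) -> tuple[LabeledStream, int]:
    """Parse a raw packet-log CSV into a stream.

    Column lookup is header-name driven, so column order is irrelevant.
    Malformed rows (unparseable clock or sensor fields) are skipped and
    counted; the skip count is returned alongside the stream.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing_cols = set(LOG_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"packet log missing columns: {sorted(missing_cols)}")

    clock = pd.to_datetime(
        df["date"].str.strip() + " " + df["time"].str.strip(), errors="coerce"
    )
    numeric = {
        chan: pd.to_numeric(df[log_col], errors="coerce")
        for log_col, chan in _LOG_TO_CHANNEL.items()
    }
    bad = clock.isna().to_numpy()
    for col in numeric.values():
        bad |= col.isna().to_numpy()
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("skipped %d malformed packet rows in %s", n_skipped, path)
    keep = ~bad
    clock = clock[keep]
    if len(clock) == 0:
        raise FormatError(f"no parseable packets in {path}")

    seconds = (clock - clock.iloc[0]).dt.total_seconds().to_numpy()
    deltas = np.diff(seconds)
    if np.any(deltas <= 0):
        row = int(np.argmax(deltas <= 0)) + 1
        raise OrderingError(f"non-monotone timestamp at packet row {row}")

    data = pd.DataFrame({"timestamp": seconds})
    for chan in CHANNEL_COLUMNS:
        data[chan] = numeric[chan][keep].to_numpy(dtype=float)
    stream = LabeledStream(data=data.reset_index(drop=True), sampling_rate=sampling_rate)
    return stream, n_skipped


def detect_missing(
    stream: LabeledStream, sampling_rate: float | None = None
) -> GapReport:
    """Count missing samples from consecutive timestamp deltas.

    Applies ``missing = round(ΔT × rate) − 1`` per consecutive packet pair,
    floored at zero; a gap-free stream reports ``total_missing = 0``.
    """
    rate = float(sampling_rate if sampling_rate is not None else stream.sampling_rate)
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    ts = stream.timestamps
    if len(ts) < 2:
        raise ValueError("need at least 2 packets to detect gaps")
    deltas = np.diff(ts)
    if np.any(deltas < 0):
        row = int(np.argmax(deltas < 0)) + 1
        raise OrderingError(f"negative timestamp delta before packet {row}")
    counts = np.maximum(np.rint(deltas * rate).astype(int) - 1, 0)
    gaps = tuple(
        (int(i), float(deltas[i]), int(counts[i])) for i in np.nonzero(counts)[0]
    )
    return GapReport(gaps=gaps, total_missing=int(counts.sum()), sampling_rate=rate)


def impute_gaps(
    stream: LabeledStream,
    report: GapReport | None = None,
    linear: bool = False,
) -> LabeledStream:
    """Fill detected gaps, restoring a regular gap-free stream.

    Every missing slot receives the average of the surviving packet before and
    after the gap (the same constant for all slots of a multi-sample gap);
    with ``linear=True`` the slots are linearly interpolated instead.
    Surviving packets are not modified.  Imputed timestamps land exactly on
    the nominal sample grid.  When the stream carries labels, imputed samples
    take the label of the nearest surviving neighbor (ties go to the packet
    after the gap).
    """
    if report is None:
        report = detect_missing(stream)
    if report.total_missing == 0:
        return stream
    rate = report.sampling_rate
    df = stream.data
    has_labels = stream.has_labels
    ts = stream.timestamps

    pieces: list[pd.DataFrame] = []
    cursor = 0
    for after_idx, _dt, m in report.gaps:
        pieces.append(df.iloc[cursor : after_idx + 1])
        before = df.iloc[after_idx]
        after = df.iloc[after_idx + 1]
        # grid-exact timestamps for the imputed slots
        base_tick = int(np.rint(ts[after_idx] * rate))
        new_ts = (base_tick + np.arange(1, m + 1)) / rate
        fill = {"timestamp": new_ts}
        for chan in CHANNEL_COLUMNS:
            v0, v1 = float(before[chan]), float(after[chan])
            if linear:
                w = np.arange(1, m + 1) / (m + 1)
                fill[chan] = v0 + w * (v1 - v0)
            else:
                fill[chan] = np.full(m, (v0 + v1) / 2.0)
        if has_labels:
            before_n = m // 2  # nearest-neighbor labels, tie toward the packet after
            fill["label"] = np.array(
                [before["label"]] * before_n + [after["label"]] * (m - before_n),
                dtype=object,
            )
            if "variation" in df.columns:
                fill["variation"] = np.array(
                    [before["variation"]] * before_n
                    + [after["variation"]] * (m - before_n),
                    dtype=object,
                )
        pieces.append(pd.DataFrame(fill))
        cursor = after_idx + 1
    pieces.append(df.iloc[cursor:])
    out = pd.concat(pieces, ignore_index=True)
    repaired = stream.with_data(out)
    if len(repaired) != len(stream) + report.total_missing:
        raise RuntimeError("imputation produced an unexpected sample count")
    return repaired


def fill_boundary(
    stream: LabeledStream,
    expected_start: float,
    expected_end: float,
) -> LabeledStream:
    """Extend a stream to an expected time range by nearest-neighbor fill.

    Loss at a stream boundary has no neighbor on one side, so the two-sided
    average is undefined; the single surviving neighbor's values are repeated.
    """
    rate = stream.sampling_rate
    df = stream.data
    ts = stream.timestamps
    pieces = []
    n_before = int(np.rint((ts[0] - expected_start) * rate))
    if n_before > 0:
        logger.info("boundary fill: %d samples before first packet", n_before)
        base_tick = int(np.rint(ts[0] * rate))
        head = pd.concat([df.iloc[[0]]] * n_before, ignore_index=True)
        head["timestamp"] = (base_tick - np.arange(n_before, 0, -1)) / rate
        pieces.append(head)
    pieces.append(df)
    n_after = int(np.rint((expected_end - ts[-1]) * rate))
    if n_after > 0:
        logger.info("boundary fill: %d samples after last packet", n_after)
        base_tick = int(np.rint(ts[-1] * rate))
        tail = pd.concat([df.iloc[[-1]]] * n_after, ignore_index=True)
        tail["timestamp"] = (base_tick + np.arange(1, n_after + 1)) / rate
        pieces.append(tail)
    if len(pieces) == 1:
        return stream
    return stream.with_data(pd.concat(pieces, ignore_index=True))


@dataclass(frozen=True)
class OutlierPolicy:
    """Physical-bounds thresholds; any violating sample is treated as missing."""

    max_accel_g: float = 8.0
    max_gyro_dps: float = 2000.0


@dataclass(frozen=True)
class RemovalLog:
    removed_indices: tuple[int, ...] = field(default_factory=tuple)

    @property
    def count(self) -> int:
        return len(self.removed_indices)


def remove_outliers(
    stream: LabeledStream, policy: OutlierPolicy | None = None
) -> tuple[LabeledStream, RemovalLog]:
    """Replace physically impossible samples via the gap-imputation rule.

    A sample is an outlier when any accelerometer axis exceeds
    ``max_accel_g`` or any gyroscope axis exceeds ``max_gyro_dps`` in
    magnitude.  Outliers are removed and refilled with the neighbor average,
    so the output stays regular.  A stream in which every sample violates the
    bounds is rejected.
    """
    if policy is None:
        policy = OutlierPolicy()
    acc = np.abs(stream.channels(("accel_x", "accel_y", "accel_z")))
    gyr = np.abs(stream.channels(("gyro_x", "gyro_y", "gyro_z")))
    bad = (acc > policy.max_accel_g).any(axis=1) | (gyr > policy.max_gyro_dps).any(axis=1)
    if not bad.any():
        return stream, RemovalLog()
    if bad.all():
        raise DataQualityError("every sample violates physical bounds")
    removed = tuple(int(i) for i in np.nonzero(bad)[0])
    logger.info("removing %d outlier samples", len(removed))
    # keep boundary coverage: if first/last samples are outliers, replace them
    # with the nearest surviving value, then treat interior outliers as gaps
    df = stream.data.copy()
    good_idx = np.nonzero(~bad)[0]
    first_good, last_good = good_idx[0], good_idx[-1]
    for i in range(first_good):
        df.iloc[i, df.columns.get_indexer(list(CHANNEL_COLUMNS))] = df.iloc[
            first_good
        ][list(CHANNEL_COLUMNS)].to_numpy(dtype=float)
    for i in range(last_good + 1, len(df)):
        df.iloc[i, df.columns.get_indexer(list(CHANNEL_COLUMNS))] = df.iloc[last_good][
            list(CHANNEL_COLUMNS)
        ].to_numpy(dtype=float)
    interior_bad = bad.copy()
    interior_bad[: first_good + 1] = False
    interior_bad[last_good:] = False
    if interior_bad.any():
        surviving = stream.with_data(df.loc[~interior_bad])
        report = detect_missing(surviving, stream.sampling_rate)
        repaired = impute_gaps(surviving, report)
        df = repaired.data
    return stream.with_data(df), RemovalLog(removed_indices=removed)
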