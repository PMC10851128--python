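"""1-second epochs, event files, and temporal alignment.

High-rate per-sample label tracks are reduced to 1-Hz epoch series by
majority vote within each second (the modal label; ties go to the class
listed first in the supplied class order).  Event files — chronological
``(onset, duration, activity)`` episode lists, the format thigh-worn
reference trackers export — expand to the same epoch representation.
Two epoch series from different devices are aligned by the integer-second
shift that maximizes label agreement.

All times are 0-based seconds from session start; an epoch covers the
half-open interval [t, t+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .activities import UNKNOWN, Taxonomy


class AlignmentError(ValueError):
    """Two epoch series share no overlapping support at any allowed shift."""


@dataclass
class EpochSeries:
    """Contiguous 1-Hz activity labels for one session from one source."""

    labels: np.ndarray  # dtype str/object, one label per second
    start_time: float = 0.0
    source: str = "sord"  # sord | activpal | observation
    taxonomy: Taxonomy | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def seconds(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.labels), dtype=float)

    def mapped(self, taxonomy: Taxonomy) -> "EpochSeries":
        """Map base-activity labels onto taxonomy classes.

        Labels already in the taxonomy's class set pass through; excluded
        activities and unrecognized labels become ``"unknown"``.
        """
        out = np.empty(len(self.labels), dtype=object)
        classes = set(taxonomy.classes)
        for i, lab in enumerate(self.labels):
            if lab in classes:
                out[i] = lab
            else:
                try:
                    cls = taxonomy.map(lab)
                except (ValueError, KeyError):
                    cls = UNKNOWN
                out[i] = cls if cls in classes else UNKNOWN
        return replace(self, labels=out, taxonomy=taxonomy)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "second": self.seconds.astype(int),
                "label": self.labels,
                "source": self.source,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EpochSeries":
        df = pd.read_csv(path, dtype={"label": str})
        src = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "sord"
        start = float(df["second"].iloc[0]) if len(df) else 0.0
        return cls(labels=df["label"].to_numpy(dtype=object), start_time=start, source=src)


def reduce_to_epochs(
    labels: np.ndarray | list,
    sampling_rate: float,
    class_order: tuple[str, ...] | list[str] | None = None,
    start_time: float = 0.0,
    source: str = "sord",
) -> EpochSeries:
    """Majority-vote reduction of per-sample labels to 1-second epochs.

    The trailing partial second is dropped.  Ties within an epoch resolve to
    the class appearing first in ``class_order`` (sorted label order when not
    given).  Input already at 1 Hz passes through unchanged.
    """
    labels = np.asarray(labels, dtype=object)
    rate = int(round(sampling_rate))
    if not np.isclose(sampling_rate, rate) or rate < 1:
        raise ValueError(f"sampling rate must be a positive integer Hz, got {sampling_rate}")
    if len(labels) < rate:
        raise ValueError("need at least one full second of samples")
    if rate == 1:
        return EpochSeries(labels=labels, start_time=start_time, source=source)

    n_epochs = len(labels) // rate
    block = labels[: n_epochs * rate].reshape(n_epochs, rate)
    order = tuple(class_order) if class_order is not None else tuple(sorted(set(labels.tolist())))
    rank = {c: k for k, c in enumerate(order)}
    out = np.empty(n_epochs, dtype=object)
    for i in range(n_epochs):
        vals, counts = np.unique(block[i].astype(str), return_counts=True)
        best = max(zip(vals, counts), key=lambda vc: (vc[1], -rank.get(vc[0], len(rank))))
        out[i] = best[0]
    return EpochSeries(labels=out, start_time=start_time, source=source)


@dataclass(frozen=True)
class EventRecord:
    """One activity episode: onset and duration in whole seconds."""

    onset: float
    duration: float
    activity: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"event duration must be positive, got {self.duration}")


def read_event_file(path: str | Path, source: str = "activpal") -> EpochSeries:
    """Expand an event CSV (onset_s, duration_s, activity) to 1-s epochs.

    Events must be chronological and non-overlapping; coverage gaps become
    explicit ``"unknown"`` epochs, which downstream comparisons exclude.
    """
    df = pd.read_csv(path, dtype={"activity": str})
    missing = {"onset_s", "duration_s", "activity"} - set(df.columns)
    if missing:
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    events = [
        EventRecord(float(r.onset_s), float(r.duration_s), str(r.activity))
        for r in df.itertuples()
    ]
    return events_to_epochs(events, source=source)


def events_to_epochs(events: list[EventRecord], source: str = "activpal") -> EpochSeries:
    if not events:
        raise ValueError("event list is empty")
    prev_end = None
    for ev in events:
        if prev_end is not None and ev.onset < prev_end:
            raise ValueError(
                f"overlapping events: episode at {ev.onset}s starts before {prev_end}s"
            )
        prev_end = ev.onset + ev.duration
    start = int(round(events[0].onset))
    end = int(round(events[-1].onset + events[-1].duration))
    labels = np.full(end - start, UNKNOWN, dtype=object)
    for ev in events:
        a = int(round(ev.onset)) - start
        b = int(round(ev.onset + ev.duration)) - start
        labels[a:b] = ev.activity
    return EpochSeries(labels=labels, start_time=float(start), source=source)


def epochs_to_events(series: EpochSeries) -> list[EventRecord]:
    """Run-length encode an epoch series back into events (unknown spans become gaps)."""
    events: list[EventRecord] = []
    labs = series.labels
    t0 = series.start_time
    i = 0
    while i < len(labs):
        j = i
        while j < len(labs) and labs[j] == labs[i]:
            j += 1
        if labs[i] != UNKNOWN:
            events.append(EventRecord(t0 + i, float(j - i), str(labs[i])))
        i = j
    return events


def write_event_file(series: EpochSeries, path: str | Path) -> None:
    events = epochs_to_events(series)
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "duration_s": [e.duration for e in events],
            "activity": [e.activity for e in events],
        }
    ).to_csv(path, index=False)


@dataclass
class AlignedPair:
    """Two epoch series trimmed to common support after shifting."""

    a: EpochSeries
    b: EpochSeries
    offset: int  # seconds added to b's clock to best match a
    agreement: float
    candidates: dict[int, float] = field(default_factory=dict, repr=False)


def align_series(a: EpochSeries, b: EpochSeries, max_shift: int = 10) -> AlignedPair:
    """Align two epoch series by the agreement-maximizing integer shift.

    The offset ``s`` compares ``a[t]`` with ``b[t - s]`` on their overlap (so
    a series delayed by d seconds relative to ``a`` is recovered with offset
    −d).  Ties break toward zero offset.  Epochs labeled unknown in either
    series do not count toward agreement.
    """
    la, lb = np.asarray(a.labels, dtype=object), np.asarray(b.labels, dtype=object)
    scores: dict[int, float] = {}
    best: tuple[float, int] | None = None
    for s in sorted(range(-int(max_shift), int(max_shift) + 1), key=lambda x: (abs(x), x)):
        # overlap of a-index t with b-index t - s
        lo = max(0, s)
        hi = min(len(la), len(lb) + s)
        if hi <= lo:
            continue
        seg_a = la[lo:hi]
        seg_b = lb[lo - s : hi - s]
        valid = (seg_a != UNKNOWN) & (seg_b != UNKNOWN)
        if not valid.any():
            continue
        agr = float(np.mean(seg_a[valid] == seg_b[valid]))
        scores[s] = agr
        if best is None or agr > best[0]:
            best = (agr, s)
    if best is None:
        raise AlignmentError("series share no valid overlap at any allowed shift")
    agr, s = best
    if agr < 0.5:
        warnings.warn(
            f"best alignment agreement is only {agr:.2f}; series may be unrelated",
            stacklevel=2,
        )
    lo = max(0, s)
    hi = min(len(la), len(lb) + s)
    a_out = replace(a, labels=la[lo:hi], start_time=a.start_time + lo)
    b_out = replace(b, labels=lb[lo - s : hi - s], start_time=a.start_time + lo)
    return AlignedPair(a=a_out, b=b_out, offset=s, agreement=agr, candidates=scores)
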