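"""Scripted activity protocols.

A :class:`ProtocolScript` is an ordered list of activity bouts, each a
(:class:`~sordkit.activities.ActivityLabel`, duration) pair.  The default
script follows the laboratory posture sequence used for validating thigh-worn
trackers: sitting, reclining, sitting, standing, walking, standing, sitting,
lying, then treadmill walking, with every bout lasting between 2 minutes and
3 minutes 30 seconds except self-paced walking, which may be shorter (a short
over-ground walk rather than a timed treadmill bout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .activities import Activity, ActivityLabel

#: Inclusive bout-duration band (seconds) for all non-self-paced bouts.
BOUT_DURATION_RANGE = (120.0, 210.0)

#: Default self-paced over-ground walking duration band (seconds).
SELF_PACED_RANGE = (45.0, 90.0)

#: Default bout order: (base activity, variation tag).
DEFAULT_SEQUENCE: tuple[tuple[Activity, str], ...] = (
    (Activity.SITTING, "upright"),
    (Activity.RECLINING, "normal-135"),
    (Activity.SITTING, "ankle-on-knee-lr"),
    (Activity.STANDING, "stand-normal"),
    (Activity.WALKING, "self-paced"),
    (Activity.STANDING, "weight-right"),
    (Activity.SITTING, "both-feet-move"),
    (Activity.LYING, "face-up"),
    (Activity.WALKING, "treadmill-4kmh"),
    (Activity.WALKING, "treadmill-6kmh"),
)


@dataclass(frozen=True)
class Bout:
    label: ActivityLabel
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"bout duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class ProtocolScript:
    """Ordered activity bouts plus optional rest insertions.

    ``rest_gaps`` lists ``(after_bout_index, seconds)`` pairs; each rest is
    realized as quiet upright sitting between the named bout and the next.
    """

    bouts: tuple[Bout, ...]
    rest_gaps: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError("protocol script must contain at least one bout")
        for idx, secs in self.rest_gaps:
            if not 0 <= idx < len(self.bouts):
                raise ValueError(f"rest gap after bout {idx}: no such bout")
            if secs <= 0:
                raise ValueError("rest duration must be positive")

    @property
    def total_duration(self) -> float:
        return sum(b.duration for b in self.bouts) + sum(s for _, s in self.rest_gaps)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "bouts": [
                {
                    "activity": b.label.value.value,
                    "variation": b.label.variation,
                    "duration_s": float(b.duration),
                }
                for b in self.bouts
            ],
            "rest_gaps": [
                {"after_bout": int(i), "duration_s": float(s)}
                for i, s in self.rest_gaps
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolScript":
        doc = yaml.safe_load(Path(path).read_text())
        bouts = tuple(
            Bout(
                ActivityLabel(Activity(b["activity"]), b.get("variation")),
                float(b["duration_s"]),
            )
            for b in doc["bouts"]
        )
        rest = tuple(
            (int(g["after_bout"]), float(g["duration_s"]))
            for g in doc.get("rest_gaps", [])
        )
        return cls(bouts=bouts, rest_gaps=rest)


def default_protocol(rng: np.random.Generator | None = None) -> ProtocolScript:
    """Build the default bout sequence.

    With an ``rng``, bout durations are drawn as whole seconds uniformly from
    the protocol band (and self-paced walking from its shorter band); without
    one, fixed representative durations are used.  Whole-second durations keep
    every bout an exact number of samples at any integer sampling rate.
    """
    lo, hi = BOUT_DURATION_RANGE
    slo, shi = SELF_PACED_RANGE
    bouts = []
    for act, var in DEFAULT_SEQUENCE:
        if var == "self-paced":
            dur = 66.0 if rng is None else float(rng.integers(int(slo), int(shi) + 1))
        else:
            dur = 165.0 if rng is None else float(rng.integers(int(lo), int(hi) + 1))
        bouts.append(Bout(ActivityLabel(act, var), dur))
    return ProtocolScript(bouts=tuple(bouts))
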