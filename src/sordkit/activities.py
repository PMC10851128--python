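"""Base activities, posture variations, and classifier label taxonomies.

Five base activities are recognized: lying, reclining, sitting, standing and
walking.  Each activity comes with a set of named sub-variations (e.g. sitting
ankle-on-knee, standing with one shoulder on a wall, treadmill walking at a
fixed speed) that alter the signal but never the base label.

A :class:`Taxonomy` maps the base activities onto the target classes of a
classifier.  Four standard taxonomies are provided:

* ``model1`` — sedentary (lying + reclining + sitting), standing, walking
* ``model2`` — sitting & reclining merged; standing; walking; lying excluded
* ``model3`` — sitting, standing, walking; reclining and lying excluded
* ``model4`` — all five activities, lying and sitting & reclining kept apart
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Activity(str, Enum):
    """One of the five base activities."""

    LYING = "lying"
    RECLINING = "reclining"
    SITTING = "sitting"
    STANDING = "standing"
    WALKING = "walking"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Named posture/gait variations and the base activity each belongs to.
VARIATIONS: dict[str, Activity] = {
    # lying
    "face-up": Activity.LYING,
    "right-shoulder": Activity.LYING,
    "face-down": Activity.LYING,
    "left-shoulder": Activity.LYING,
    # reclining
    "normal-135": Activity.RECLINING,
    "left-leg-over-right": Activity.RECLINING,
    "right-leg-over-left": Activity.RECLINING,
    # sitting
    "upright": Activity.SITTING,
    "ankle-on-knee-lr": Activity.SITTING,
    "ankle-on-knee-rl": Activity.SITTING,
    "right-foot-move": Activity.SITTING,
    "left-foot-move": Activity.SITTING,
    "both-feet-move": Activity.SITTING,
    "elbows-on-legs": Activity.SITTING,
    "outstretched-legs": Activity.SITTING,
    # standing
    "stand-normal": Activity.STANDING,
    "weight-right": Activity.STANDING,
    "weight-left": Activity.STANDING,
    "right-shoulder-wall": Activity.STANDING,
    "left-shoulder-wall": Activity.STANDING,
    # walking
    "self-paced": Activity.WALKING,
    "treadmill-4kmh": Activity.WALKING,
    "treadmill-6kmh": Activity.WALKING,
}


@dataclass(frozen=True)
class ActivityLabel:
    """A base activity plus an optional variation tag.

    The variation, when given, must map to the base activity.
    """

    value: Activity
    variation: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.value, Activity):
            object.__setattr__(self, "value", Activity(self.value))
        if self.variation is not None:
            base = VARIATIONS.get(self.variation)
            if base is None:
                raise ValueError(f"unknown variation tag: {self.variation!r}")
            if base is not self.value:
                raise ValueError(
                    f"variation {self.variation!r} belongs to {base.value}, "
                    f"not {self.value.value}"
                )


#: Sentinel class name for activities a taxonomy does not score.
EXCLUDED = "excluded"

#: Label used for epochs outside any known class (e.g. event-file gaps).
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Taxonomy:
    """Mapping from the five base activities to classifier target classes."""

    name: str
    classes: tuple[str, ...]
    mapping: dict[Activity, str] = field(hash=False)

    def __post_init__(self) -> None:
        for act in Activity:
            if act not in self.mapping:
                raise ValueError(f"taxonomy {self.name}: no mapping for {act.value}")
        for act, cls in self.mapping.items():
            if cls != EXCLUDED and cls not in self.classes:
                raise ValueError(
                    f"taxonomy {self.name}: {act.value} maps to unknown class {cls!r}"
                )

    def map(self, activity: Activity | str) -> str:
        """Class name for a base activity, or ``"excluded"``."""
        return self.mapping[Activity(activity)]

    def class_index(self, cls: str) -> int:
        return self.classes.index(cls)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _tx(name: str, classes: tuple[str, ...], mapping: dict[Activity, str]) -> Taxonomy:
    return Taxonomy(name=name, classes=classes, mapping=mapping)


TAXONOMIES: dict[str, Taxonomy] = {
    "model1": _tx(
        "model1",
        ("sedentary", "standing", "walking"),
        {
            Activity.LYING: "sedentary",
            Activity.RECLINING: "sedentary",
            Activity.SITTING: "sedentary",
            Activity.STANDING: "standing",
            Activity.WALKING: "walking",
        },
    ),
    "model2": _tx(
        "model2",
        ("sitting_reclining", "standing", "walking"),
        {
            Activity.LYING: EXCLUDED,
            Activity.RECLINING: "sitting_reclining",
            Activity.SITTING: "sitting_reclining",
            Activity.STANDING: "standing",
            Activity.WALKING: "walking",
        },
    ),
    "model3": _tx(
        "model3",
        ("sitting", "standing", "walking"),
        {
            Activity.LYING: EXCLUDED,
            Activity.RECLINING: EXCLUDED,
            Activity.SITTING: "sitting",
            Activity.STANDING: "standing",
            Activity.WALKING: "walking",
        },
    ),
    "model4": _tx(
        "model4",
        ("lying", "sitting_reclining", "standing", "walking"),
        {
            Activity.LYING: "lying",
            Activity.RECLINING: "sitting_reclining",
            Activity.SITTING: "sitting_reclining",
            Activity.STANDING: "standing",
            Activity.WALKING: "walking",
        },
    ),
}


def get_taxonomy(name: str) -> Taxonomy:
    try:
        return TAXONOMIES[name]
    except KeyError:
        raise KeyError(
            f"unknown taxonomy {name!r}; choose from {sorted(TAXONOMIES)}"
        ) from None
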