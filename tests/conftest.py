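"""Shared fixtures: small, fast synthetic sessions for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from sordkit import (
    Activity,
    ActivityLabel,
    Bout,
    NoiseModel,
    ProtocolScript,
    simulate_session,
)


def short_script(*bouts: tuple[str, str | None, float]) -> ProtocolScript:
    """Build a protocol from (activity, variation, seconds) triples."""
    return ProtocolScript(
        bouts=tuple(
            Bout(ActivityLabel(Activity(a), v), d) for a, v, d in bouts
        )
    )


@pytest.fixture(scope="session")
def mini_script() -> ProtocolScript:
    """A 2-minute miniature of the full protocol (whole-second bouts)."""
    return short_script(
        ("sitting", "upright", 20.0),
        ("reclining", "normal-135", 16.0),
        ("standing", "stand-normal", 20.0),
        ("walking", "treadmill-4kmh", 24.0),
        ("standing", "weight-right", 12.0),
        ("lying", "face-up", 16.0),
        ("walking", "treadmill-6kmh", 12.0),
    )


@pytest.fixture(scope="session")
def mini_stream(mini_script):
    return simulate_session(mini_script, seed=123)


@pytest.fixture(scope="session")
def quiet_standing_stream():
    """Noise-free single standing bout: pure static-posture physics."""
    return simulate_session(
        short_script(("standing", "stand-normal", 10.0)),
        seed=0,
        noise=NoiseModel.none(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
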