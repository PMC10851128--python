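"""Run configuration, seed fan-out, and manifests.

One :class:`RunConfig` drives the whole pipeline.  A single global seed fans
out to per-stage seeds through a documented scheme — the stage seed is drawn
from ``numpy.random.SeedSequence([seed, crc32(stage_name)])`` — so each stage
(simulation, packet-loss injection, splitting, training, reference device) is
independently reproducible.  Every output manifest records the SHA-256 hash of
the canonical config JSON, making mixed-run outputs detectable.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import TrainingConfig, WindowSpec


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full simulate→validate run depends on."""

    seed: int = 42
    sampling_rate: float = 25.0
    taxonomy: str = "model2"
    n_participants: int = 15
    split_sizes: tuple[int, int, int] = (6, 1, 7)
    window: WindowSpec = field(default_factory=WindowSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    loss_rate: float = 0.0
    burst_mean: float = 3.0
    max_align_shift: int = 10
    #: reference-device error model; empty dict + zero lag = perfect reference
    reference_confusion: dict = field(default_factory=dict)
    reference_onset_lag_s: float = 0.0
    write_raw_csv: bool = False
    #: scales every bout duration (rounded to whole seconds, min 2 s);
    #: 1.0 = the full protocol. Intended for quick smoke runs only.
    protocol_scale: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_sizes"] = list(self.split_sizes)
        d["window"]["channels"] = list(self.window.channels)
        d["training"]["conv_filters"] = list(self.training.conv_filters)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "window" in d and isinstance(d["window"], dict):
            w = dict(d["window"])
            w["channels"] = tuple(w.get("channels", ("accel", "gyro", "angle")))
            d["window"] = WindowSpec(**w)
        if "training" in d and isinstance(d["training"], dict):
            t = dict(d["training"])
            if "conv_filters" in t:
                t["conv_filters"] = tuple(t["conv_filters"])
            d["training"] = TrainingConfig(**t)
        if "split_sizes" in d:
            d["split_sizes"] = tuple(d["split_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
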