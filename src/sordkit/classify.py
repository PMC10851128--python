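"""Sliding-window activity classification.

Windows of 35 consecutive samples (1.4 s at 25 Hz) are cut from regular
streams and labeled by the taxonomy class of their **final** sample — a causal
convention matching a device that classifies the present moment from the
recent past.  Splitting into train/validation/test is always by participant
(default 6/1/7), never by window, so no subject's data leaks across sets.

The classifier itself is the CNN+GRU in :mod:`sordkit.nn`: per-channel
z-normalization (statistics from the training set only), inverse-frequency
class weights, Adam, early stopping on validation loss, best-checkpoint
selection.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .activities import EXCLUDED, Taxonomy, get_taxonomy
from .nn import CNNGRU, Adam
from .stream import LabeledStream

#: Channel-group → stream columns.
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "accel": ("accel_x", "accel_y", "accel_z"),
    "gyro": ("gyro_x", "gyro_y", "gyro_z"),
    "mag": ("mag_x", "mag_y", "mag_z"),
    "angle": ("angle",),
}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry and channel selection."""

    length: int = 35
    stride: int = 1
    channels: tuple[str, ...] = ("accel", "gyro", "angle")

    def __post_init__(self) -> None:
        if self.length < 1 or self.stride < 1:
            raise ValueError("window length and stride must be >= 1")
        unknown = set(self.channels) - set(CHANNEL_GROUPS)
        if unknown:
            raise ValueError(f"unknown channel groups: {sorted(unknown)}")

    @property
    def columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for group in self.channels:
            cols.extend(CHANNEL_GROUPS[group])
        return tuple(cols)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint participant-level train/validation/test assignment."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("train/val/test participant sets must be disjoint")


def split_participants(
    ids: list[str] | tuple[str, ...],
    sizes: tuple[int, int, int] = (6, 1, 7),
    seed: int = 0,
) -> SplitSpec:
    """Random disjoint participant assignment, deterministic under the seed."""
    ids = sorted(set(ids))
    if len(ids) < sum(sizes):
        raise ValueError(
            f"need at least {sum(sizes)} participants for sizes {sizes}, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    a, b, c = sizes
    return SplitSpec(
        train_ids=tuple(perm[:a]),
        val_ids=tuple(perm[a : a + b]),
        test_ids=tuple(perm[a + b : a + b + c]),
    )


def make_windows(
    stream: LabeledStream,
    spec: WindowSpec,
    taxonomy: Taxonomy | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Cut labeled windows from a regular stream.

    Returns ``(X, y, end_indices)``: window tensor (n, length, channels),
    integer class targets (or None when the stream is unlabeled or no taxonomy
    is given), and the stream index of each window's final sample.  Windows
    whose final sample maps to an excluded activity are dropped.
    """
    if not stream.is_regular():
        raise ValueError("stream must be regular and gap-free; run ingest first")
    cols = spec.columns
    n = len(stream)
    if n < spec.length:
        warnings.warn(
            f"stream has {n} samples, shorter than one {spec.length}-sample window",
            stacklevel=2,
        )
        return (
            np.empty((0, spec.length, len(cols))),
            np.empty(0, dtype=int) if taxonomy is not None and stream.has_labels else None,
            np.empty(0, dtype=int),
        )
    mat = stream.channels(cols)
    view = np.lib.stride_tricks.sliding_window_view(mat, spec.length, axis=0)
    # view: (n-length+1, C, length) → select strided starts
    starts = np.arange(0, n - spec.length + 1, spec.stride)
    ends = starts + spec.length - 1
    x = view[starts].transpose(0, 2, 1).astype(float)

    y = None
    if taxonomy is not None and stream.has_labels:
        labs = stream.labels.to_numpy()[ends]
        classes = [taxonomy.map(lab) for lab in labs]
        keep = np.array([c != EXCLUDED for c in classes])
        x = x[keep]
        ends = ends[keep]
        y = np.array([taxonomy.class_index(c) for c, k in zip(classes, keep) if k])
    return x, y, ends


@dataclass
class TrainingConfig:
    """Training hyperparameters (pinned defaults)."""

    max_epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 5  # early stopping on validation loss
    train_stride: int = 10  # window stride for the training set
    val_stride: int = 10
    conv_filters: tuple[int, int] = (32, 64)
    kernel: int = 5
    hidden: int = 64


@dataclass
class TrainedClassifier:
    """A trained CNN+GRU plus everything needed to apply it."""

    taxonomy: Taxonomy
    window_spec: WindowSpec
    model: CNNGRU
    norm_mean: np.ndarray  # per-channel, training data only
    norm_scale: np.ndarray
    config: TrainingConfig
    seed: int
    training_log: list[dict] = field(default_factory=list)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean) / self.norm_scale

    # ------------------------------------------------------------------ io

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (metadata)."""
        prefix = Path(prefix)
        arrays = {f"param_{k}": v for k, v in self.model.params.items()}
        arrays["norm_mean"] = self.norm_mean
        arrays["norm_scale"] = self.norm_scale
        np.savez(prefix.with_suffix(".npz"), **arrays)
        meta = {
            "taxonomy": self.taxonomy.name,
            "window_spec": asdict(self.window_spec),
            "config": asdict(self.config),
            "seed": self.seed,
            "classes": list(self.taxonomy.classes),
            "training_log": self.training_log,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedClassifier":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = np.load(prefix.with_suffix(".npz"))
        taxonomy = get_taxonomy(meta["taxonomy"])
        ws = meta["window_spec"]
        spec = WindowSpec(ws["length"], ws["stride"], tuple(ws["channels"]))
        cfgd = dict(meta["config"])
        cfgd["conv_filters"] = tuple(cfgd["conv_filters"])
        cfg = TrainingConfig(**cfgd)
        model = CNNGRU(
            n_channels=len(spec.columns),
            n_classes=taxonomy.n_classes,
            window_length=spec.length,
            conv_filters=cfg.conv_filters,
            kernel=cfg.kernel,
            hidden=cfg.hidden,
        )
        model.params = {
            k.removeprefix("param_"): data[k] for k in data.files if k.startswith("param_")
        }
        return cls(
            taxonomy=taxonomy,
            window_spec=spec,
            model=model,
            norm_mean=data["norm_mean"],
            norm_scale=data["norm_scale"],
            config=cfg,
            seed=int(meta["seed"]),
            training_log=list(meta["training_log"]),
        )


def train_classifier(
    train_streams: list[LabeledStream],
    val_streams: list[LabeledStream],
    taxonomy: Taxonomy,
    window_spec: WindowSpec | None = None,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Train the CNN+GRU on participant-level train/validation stream sets.

    Returns the checkpoint with the best validation loss.  Fully seeded: the
    same inputs and seed reproduce the training trace.
    """
    if window_spec is None:
        window_spec = WindowSpec()
    if config is None:
        config = TrainingConfig()
    train_pids = {s.participant_id for s in train_streams}
    val_pids = {s.participant_id for s in val_streams}
    if train_pids & val_pids:
        raise ValueError(f"participants in both train and val: {train_pids & val_pids}")

    tr_spec = WindowSpec(window_spec.length, config.train_stride, window_spec.channels)
    va_spec = WindowSpec(window_spec.length, config.val_stride, window_spec.channels)
    xs, ys = [], []
    for s in train_streams:
        x, y, _ = make_windows(s, tr_spec, taxonomy)
        xs.append(x)
        ys.append(y)
    x_train = np.concatenate(xs)
    y_train = np.concatenate(ys)
    xs, ys = [], []
    for s in val_streams:
        x, y, _ = make_windows(s, va_spec, taxonomy)
        xs.append(x)
        ys.append(y)
    x_val = np.concatenate(xs)
    y_val = np.concatenate(ys)

    present = np.unique(y_train)
    for k, cls in enumerate(taxonomy.classes):
        if k not in present:
            raise ValueError(f"taxonomy class {cls!r} absent from training data")

    # normalization statistics from the training windows only
    mean = x_train.mean(axis=(0, 1))
    scale = x_train.std(axis=(0, 1))
    scale[scale < 1e-12] = 1.0
    x_train = (x_train - mean) / scale
    x_val = (x_val - mean) / scale

    # inverse-frequency class weights
    counts = np.bincount(y_train, minlength=taxonomy.n_classes).astype(float)
    class_w = counts.sum() / (taxonomy.n_classes * counts)
    sample_w = class_w[y_train]

    rng = np.random.default_rng(seed)
    model = CNNGRU(
        n_channels=x_train.shape[2],
        n_classes=taxonomy.n_classes,
        window_length=window_spec.length,
        conv_filters=config.conv_filters,
        kernel=config.kernel,
        hidden=config.hidden,
    )
    model.init_params(rng)
    opt = Adam(lr=config.learning_rate)

    def val_loss() -> float:
        probs = model.predict_proba(x_val)
        nll = -np.log(np.clip(probs[np.arange(len(y_val)), y_val], 1e-300, None))
        return float(nll.mean())

    log: list[dict] = []
    best = {"loss": np.inf, "params": copy.deepcopy(model.params), "epoch": -1}
    stall = 0
    n = len(y_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            loss, grads = model.loss_and_grads(x_train[idx], y_train[idx], sample_w[idx])
            opt.step(model.params, grads)
            total += loss
            batches += 1
        vl = val_loss()
        log.append({"epoch": epoch, "train_loss": total / batches, "val_loss": vl})
        if vl < best["loss"] - 1e-6:
            best = {"loss": vl, "params": copy.deepcopy(model.params), "epoch": epoch}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.params = best["params"]

    return TrainedClassifier(
        taxonomy=taxonomy,
        window_spec=window_spec,
        model=model,
        norm_mean=mean,
        norm_scale=scale,
        config=config,
        seed=seed,
        training_log=log,
    )


def predict_stream(
    clf: TrainedClassifier, stream: LabeledStream
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class labels and probabilities for a regular stream.

    The first prediction becomes available once one full window has been
    seen (the processing-buffer warm-up); earlier samples are back-filled
    from that first prediction.  Returns ``(labels, probs)`` with one row per
    stream sample.
    """
    cols = clf.window_spec.columns
    missing = set(cols) - set(stream.data.columns)
    if missing:
        raise ValueError(f"stream lacks channels required by the model: {sorted(missing)}")
    length = clf.window_spec.length
    n = len(stream)
    if n < length:
        warnings.warn("stream shorter than one window; no predictions", stacklevel=2)
        return np.empty(0, dtype=object), np.empty((0, clf.taxonomy.n_classes))

    mat = (stream.channels(cols) - clf.norm_mean) / clf.norm_scale
    view = np.lib.stride_tricks.sliding_window_view(mat, length, axis=0)
    n_windows = view.shape[0]
    probs_w = np.empty((n_windows, clf.taxonomy.n_classes))
    batch = 4096
    for i in range(0, n_windows, batch):
        chunk = view[i : i + batch].transpose(0, 2, 1).astype(float)
        probs_w[i : i + batch] = clf.model.predict_proba(chunk)

    probs = np.empty((n, clf.taxonomy.n_classes))
    probs[length - 1 :] = probs_w
    probs[: length - 1] = probs_w[0]  # warm-up back-fill
    idx = probs.argmax(axis=1)
    labels = np.array([clf.taxonomy.classes[k] for k in idx], dtype=object)
    return labels, probs
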