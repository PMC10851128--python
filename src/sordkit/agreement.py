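"""Validation statistics: confusion metrics and Bland-Altman agreement.

Confusion matrices follow the rows = predicted, columns = actual convention.
Per-class accuracy, sensitivity and specificity are one-vs-rest:

    sensitivity = TP / (TP + FN)      specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total

Agreement between the index device and a reference uses the Bland-Altman
method on per-participant percent-time: for each participant the difference
``d = reference − index`` is formed (positive = the index device
underestimates), the mean difference is the systematic bias, and the limits
of agreement are ``bias ± 1.96 × SD(d)`` with the sample (n−1) standard
deviation.  A class passes the predefined acceptability screen when both
limits fall within ±10 percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .activities import UNKNOWN, Taxonomy
from .epochs import EpochSeries


@dataclass
class ConfusionMatrix:
    """Epoch counts, rows = predicted class, columns = actual class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for {k} classes")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion(
    pred: EpochSeries, truth: EpochSeries, taxonomy: Taxonomy
) -> ConfusionMatrix:
    """Tally predicted-vs-actual epochs for two aligned series.

    Both series are mapped onto the taxonomy's classes first; epochs that are
    unknown (or excluded) in either series are dropped pairwise.
    """
    if len(pred) != len(truth):
        raise ValueError(
            f"series must be aligned to equal length, got {len(pred)} vs {len(truth)}"
        )
    p = pred.mapped(taxonomy).labels
    t = truth.mapped(taxonomy).labels
    valid = (p != UNKNOWN) & (t != UNKNOWN)
    index = {c: k for k, c in enumerate(taxonomy.classes)}
    pi = np.array([index[c] for c in p[valid]], dtype=int)
    ti = np.array([index[c] for c in t[valid]], dtype=int)
    counts = np.zeros((taxonomy.n_classes, taxonomy.n_classes), dtype=np.int64)
    np.add.at(counts, (pi, ti), 1)
    return ConfusionMatrix(counts=counts, classes=taxonomy.classes)


def class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """One-vs-rest accuracy, sensitivity, specificity per class.

    Ratios with a zero denominator are reported as NaN with a warning.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    total = cm.total
    out: dict[str, dict[str, float]] = {}
    for k, cls in enumerate(cm.classes):
        tp = float(cm.counts[k, k])
        fn = float(cm.counts[:, k].sum() - tp)  # actual cls, predicted other
        fp = float(cm.counts[k, :].sum() - tp)  # predicted cls, actually other
        tn = float(total - tp - fn - fp)
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        if np.isnan(sens):
            warnings.warn(f"sensitivity undefined for {cls!r}: class absent from truth",
                          stacklevel=2)
        if np.isnan(spec):
            warnings.warn(f"specificity undefined for {cls!r}", stacklevel=2)
        out[cls] = {
            "accuracy": (tp + tn) / total,
            "sensitivity": sens,
            "specificity": spec,
        }
    return out


def percent_time(series: EpochSeries, cls: str) -> float:
    """Percent of comparable (non-unknown) epochs labeled ``cls``."""
    labels = series.labels
    valid = labels != UNKNOWN
    n = int(valid.sum())
    if n == 0:
        raise ValueError("series has no comparable epochs")
    return 100.0 * float((labels[valid] == cls).sum()) / n


@dataclass
class BlandAltman:
    """Bias and limits of agreement for one activity class."""

    mean_bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray = field(repr=False)
    acceptable: bool = False
    multiplier: float = 1.96
    acceptability_band: float = 10.0

    @property
    def n(self) -> int:
        return len(self.differences)


def bland_altman(
    index: np.ndarray | list[float],
    reference: np.ndarray | list[float],
    multiplier: float = 1.96,
    acceptability_band: float = 10.0,
) -> BlandAltman:
    """Bland-Altman agreement between paired per-participant values.

    Differences are ``reference − index``, so a positive bias means the index
    device underestimates.  Limits of agreement use the sample SD (n−1).
    """
    index = np.asarray(index, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if index.shape != reference.shape:
        raise ValueError("paired vectors must have equal length")
    if index.ndim != 1 or len(index) < 2:
        raise ValueError("need at least 2 paired observations (SD undefined below)")
    d = reference - index
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - multiplier * sd, bias + multiplier * sd
    return BlandAltman(
        mean_bias=bias,
        loa_low=lo,
        loa_high=hi,
        differences=d,
        acceptable=bool(-acceptability_band <= lo and hi <= acceptability_band),
        multiplier=multiplier,
        acceptability_band=acceptability_band,
    )


@dataclass
class ValidationReport:
    """Pooled confusion metrics plus per-class Bland-Altman agreement."""

    taxonomy: Taxonomy
    confusion: ConfusionMatrix
    metrics: dict[str, dict[str, float]]
    agreement: dict[str, BlandAltman] | None
    percent_times: dict[str, dict[str, tuple[float, float]]]  # pid → cls → (index, ref)
    seconds_diffs: dict[str, list[float]]  # cls → per-participant (ref − index) seconds

    def to_json_dict(self) -> dict:
        return {
            "taxonomy": self.taxonomy.name,
            "classes": list(self.taxonomy.classes),
            "confusion_rows_predicted": self.confusion.counts.tolist(),
            "metrics": self.metrics,
            "agreement": {
                cls: {
                    "mean_bias_pct": ba.mean_bias,
                    "loa_low_pct": ba.loa_low,
                    "loa_high_pct": ba.loa_high,
                    "acceptable_within_10pct": ba.acceptable,
                    "n_participants": ba.n,
                }
                for cls, ba in (self.agreement or {}).items()
            },
        }


def validate_session_set(
    pred: dict[str, EpochSeries],
    reference: dict[str, EpochSeries],
    taxonomy: Taxonomy,
) -> ValidationReport:
    """Full validation report over a set of participants.

    ``pred`` and ``reference`` map participant id → aligned epoch series.
    Confusion counts are pooled over participants; per-participant
    percent-times feed one Bland-Altman per class.  With a single participant
    the Bland-Altman block is omitted (SD undefined) but confusion metrics are
    still produced.
    """
    pids = sorted(pred)
    if sorted(reference) != pids:
        raise ValueError("pred and reference must cover the same participants")
    if not pids:
        raise ValueError("no participants to validate")

    pooled: ConfusionMatrix | None = None
    pct: dict[str, dict[str, tuple[float, float]]] = {}
    sec_diffs: dict[str, list[float]] = {cls: [] for cls in taxonomy.classes}
    for pid in pids:
        cm = confusion(pred[pid], reference[pid], taxonomy)
        pooled = cm if pooled is None else pooled + cm
        p_m = pred[pid].mapped(taxonomy)
        r_m = reference[pid].mapped(taxonomy)
        # epochs unknown/excluded in either series drop pairwise before
        # all statistics (otherwise the two denominators diverge)
        valid = (p_m.labels != UNKNOWN) & (r_m.labels != UNKNOWN)
        if not valid.any():
            raise ValueError(f"participant {pid}: no comparable epochs")
        p_lab, r_lab = p_m.labels[valid], r_m.labels[valid]
        n_valid = int(valid.sum())
        pct[pid] = {}
        for cls in taxonomy.classes:
            p_sec = float((p_lab == cls).sum())
            r_sec = float((r_lab == cls).sum())
            pct[pid][cls] = (100.0 * p_sec / n_valid, 100.0 * r_sec / n_valid)
            sec_diffs[cls].append(r_sec - p_sec)

    metrics = class_metrics(pooled)
    agreement: dict[str, BlandAltman] | None
    if len(pids) >= 2:
        agreement = {}
        for cls in taxonomy.classes:
            idx = [pct[pid][cls][0] for pid in pids]
            ref = [pct[pid][cls][1] for pid in pids]
            agreement[cls] = bland_altman(idx, ref)
    else:
        warnings.warn("single participant: Bland-Altman requires n >= 2; skipped",
                      stacklevel=2)
        agreement = None

    return ValidationReport(
        taxonomy=taxonomy,
        confusion=pooled,
        metrics=metrics,
        agreement=agreement,
        percent_times=pct,
        seconds_diffs=sec_diffs,
    )
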