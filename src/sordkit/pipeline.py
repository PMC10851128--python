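"""End-to-end orchestration: simulate → ingest → train → predict → validate.

``run_pipeline`` executes the whole validation experiment for one
:class:`~sordkit.config.RunConfig`:

1. simulate one labeled 25-Hz session per participant (each with their own
   protocol-script draw and signal idiosyncrasies);
2. optionally degrade the streams with bursty packet loss and repair them by
   timestamp-based gap imputation;
3. split participants into train/validation/test sets, train the CNN+GRU
   under the configured taxonomy, and predict the held-out streams;
4. reduce predictions to 1-second epochs, build the reference epoch series
   (direct-observation ground truth, and an imperfect second device when an
   error model is configured), align, and compute the validation report.

All randomness derives from the config's single seed via per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .activities import get_taxonomy
from .agreement import ValidationReport, validate_session_set
from .classify import TrainedClassifier, predict_stream, split_participants, train_classifier
from .config import RunConfig, stage_seed
from .epochs import EpochSeries, align_series, reduce_to_epochs
from .ingest import detect_missing, impute_gaps
from .protocol import default_protocol
from .stream import LabeledStream, write_packet_log
from .synthetic import (
    ReferenceErrorModel,
    inject_packet_loss,
    make_profiles,
    simulate_reference_device,
    simulate_session,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunResult:
    """Everything a pipeline run produced."""

    config: RunConfig
    split: object
    classifier: TrainedClassifier
    report: ValidationReport
    reference_report: ValidationReport | None
    epoch_accuracy: float
    pred_epochs: dict[str, EpochSeries] = field(repr=False, default_factory=dict)
    truth_epochs: dict[str, EpochSeries] = field(repr=False, default_factory=dict)
    streams: dict[str, LabeledStream] = field(repr=False, default_factory=dict)

    def manifest(self) -> dict:
        m = {
            "config_hash": self.config.hash(),
            "config": self.config.to_dict(),
            "split": {
                "train": list(self.split.train_ids),
                "val": list(self.split.val_ids),
                "test": list(self.split.test_ids),
            },
            "epoch_accuracy": self.epoch_accuracy,
            "report": self.report.to_json_dict(),
        }
        if self.reference_report is not None:
            m["reference_report"] = self.reference_report.to_json_dict()
        return m


def simulate_cohort(config: RunConfig) -> dict[str, LabeledStream]:
    """One labeled gap-free session per participant."""
    profiles = make_profiles(config.n_participants, stage_seed(config.seed, "profiles"))
    streams: dict[str, LabeledStream] = {}
    for i, prof in enumerate(profiles):
        script = default_protocol(
            np.random.default_rng(stage_seed(config.seed, f"protocol/{prof.participant_id}"))
        )
        if config.protocol_scale != 1.0:
            from .protocol import Bout, ProtocolScript

            script = ProtocolScript(
                bouts=tuple(
                    Bout(b.label, max(2.0, round(b.duration * config.protocol_scale)))
                    for b in script.bouts
                )
            )
        streams[prof.participant_id] = simulate_session(
            script,
            prof,
            seed=stage_seed(config.seed, f"session/{prof.participant_id}"),
            sampling_rate=config.sampling_rate,
        )
    return streams


def degrade_and_repair(
    streams: dict[str, LabeledStream], config: RunConfig
) -> tuple[dict[str, LabeledStream], dict[str, int]]:
    """Inject bursty packet loss and repair it by gap imputation."""
    repaired: dict[str, LabeledStream] = {}
    missing_counts: dict[str, int] = {}
    for pid, s in streams.items():
        lossy = inject_packet_loss(
            s, config.loss_rate, config.burst_mean,
            seed=stage_seed(config.seed, f"loss/{pid}"),
        )
        report = detect_missing(lossy, config.sampling_rate)
        missing_counts[pid] = report.total_missing
        repaired[pid] = impute_gaps(lossy, report)
    return repaired, missing_counts


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full experiment; optionally write all artifacts to ``outdir``."""
    taxonomy = get_taxonomy(config.taxonomy)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        truth_streams = simulate_cohort(config)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError(f"simulate: {e}") from e

    streams = truth_streams
    if config.loss_rate > 0:
        try:
            stage("ingest")
            streams, _ = degrade_and_repair(truth_streams, config)
        except Exception as e:
            raise PipelineError(f"ingest: {e}") from e

    try:
        stage("split+train")
        split = split_participants(
            list(streams), config.split_sizes, stage_seed(config.seed, "split")
        )
        clf = train_classifier(
            [streams[p] for p in split.train_ids],
            [streams[p] for p in split.val_ids],
            taxonomy,
            window_spec=config.window,
            config=config.training,
            seed=stage_seed(config.seed, "train"),
        )
    except Exception as e:
        raise PipelineError(f"train: {e}") from e

    try:
        stage("predict+epochs")
        pred_epochs: dict[str, EpochSeries] = {}
        truth_epochs: dict[str, EpochSeries] = {}
        ref_epochs: dict[str, EpochSeries] = {}
        want_reference = bool(config.reference_confusion) or config.reference_onset_lag_s > 0
        error_model = ReferenceErrorModel(
            confusion=dict(config.reference_confusion),
            onset_lag_s=config.reference_onset_lag_s,
        )
        for pid in split.test_ids:
            labels, _ = predict_stream(clf, streams[pid])
            pred_epochs[pid] = reduce_to_epochs(
                labels, config.sampling_rate, class_order=taxonomy.classes, source="sord"
            )
            # direct-observation ground truth, mapped onto the taxonomy so
            # alignment compares like with like (excluded activities → unknown)
            truth_epochs[pid] = simulate_reference_device(truth_streams[pid]).mapped(taxonomy)
            truth_epochs[pid].source = "observation"
            if want_reference:
                ref_epochs[pid] = simulate_reference_device(
                    truth_streams[pid],
                    error_model,
                    seed=stage_seed(config.seed, f"reference/{pid}"),
                ).mapped(taxonomy)
            # temporal alignment (a no-op offset for simulated clocks)
            pair = align_series(pred_epochs[pid], truth_epochs[pid], config.max_align_shift)
            pred_epochs[pid], truth_epochs[pid] = pair.a, pair.b
    except Exception as e:
        raise PipelineError(f"predict: {e}") from e

    try:
        stage("agreement")
        report = validate_session_set(pred_epochs, truth_epochs, taxonomy)
        acc = float(np.trace(report.confusion.counts)) / report.confusion.total
        reference_report = None
        if want_reference:
            pred_vs_ref, trimmed_ref = {}, {}
            for pid in ref_epochs:
                pair = align_series(pred_epochs[pid], ref_epochs[pid], config.max_align_shift)
                pred_vs_ref[pid], trimmed_ref[pid] = pair.a, pair.b
            reference_report = validate_session_set(pred_vs_ref, trimmed_ref, taxonomy)
    except Exception as e:
        raise PipelineError(f"agreement: {e}") from e

    result = RunResult(
        config=config,
        split=split,
        classifier=clf,
        report=report,
        reference_report=reference_report,
        epoch_accuracy=acc,
        pred_epochs=pred_epochs,
        truth_epochs=truth_epochs,
        streams=streams,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(result.manifest(), indent=2))
        clf.save(outdir / "classifier")
        for pid, ep in pred_epochs.items():
            ep.to_csv(outdir / f"pred_epochs_{pid}.csv")
        if config.write_raw_csv:
            for pid, s in truth_streams.items():
                write_packet_log(
                    s, outdir / f"raw_{pid}.csv", outdir / f"labels_{pid}.csv"
                )
        try:
            from .plots import bland_altman_plot, confusion_plot

            confusion_plot(report.confusion, outdir / "confusion.png")
            if report.agreement:
                bland_altman_plot(
                    report.agreement, report.percent_times, outdir / "bland_altman.png"
                )
        except Exception:  # plotting must never fail a run
            logger.exception("plotting failed")
    return result
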