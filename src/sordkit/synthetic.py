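"""Synthetic thigh-worn IMU sessions.

Generates labeled 25-Hz sensor streams for a scripted posture protocol, for
use when real recordings are unavailable.  The signal model is deliberately
simple but class-separable:

* **Static postures** — the accelerometer reads gravity projected onto the
  device frame for a thigh at inclination θ from vertical with roll φ about
  the thigh axis: ``a = [cos θ, sin θ sin φ, sin θ cos φ]`` g (unit magnitude
  by construction).  Standing and walking keep the thigh near vertical,
  sitting and lying near horizontal, reclining intermediate (a 135° chair).
  Sitting and face-up lying are therefore nearly indistinguishable from the
  thigh alone — a deliberate property of thigh-worn sensing.
* **Walking** — thigh inclination oscillates at the step cadence (higher
  speed → higher cadence), with an impact component in the longitudinal
  accelerometer axis and the matching pitch rate in the gyroscope.
* **Fidgeting** — variation-dependent Poisson-arriving damped sinusoid
  bursts that perturb the signal without changing the base label.
* **Noise** — additive Gaussian per channel; the magnetometer sees a
  constant earth field rotated into the device frame plus noise.

Bout transitions last 1–2 s (linear posture ramp) and are labeled with the
destination activity, so ground-truth totals equal the scripted durations
exactly.  ``inject_packet_loss`` and ``simulate_reference_device`` produce
the degraded stream and the imperfect second-device epoch series used for
validation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activities import Activity, ActivityLabel
from .epochs import EpochSeries, epochs_to_events, events_to_epochs, reduce_to_epochs
from .protocol import ProtocolScript
from .stream import LabeledStream

#: Mean thigh inclination from vertical (degrees) per base activity.
POSTURE_ANGLES: dict[Activity, float] = {
    Activity.LYING: 90.0,
    Activity.RECLINING: 60.0,
    Activity.SITTING: 87.0,
    Activity.STANDING: 8.0,
    Activity.WALKING: 12.0,
}

#: Per-variation (inclination offset deg, roll deg, fidget bursts per second).
VARIATION_EFFECTS: dict[str, tuple[float, float, float]] = {
    "face-up": (0.0, 0.0, 0.0),
    "right-shoulder": (0.0, 80.0, 0.0),
    "face-down": (0.0, 180.0, 0.0),
    "left-shoulder": (0.0, -80.0, 0.0),
    "normal-135": (0.0, 0.0, 0.0),
    "left-leg-over-right": (5.0, 10.0, 0.02),
    "right-leg-over-left": (5.0, -10.0, 0.02),
    "upright": (0.0, 0.0, 0.01),
    "ankle-on-knee-lr": (-8.0, 20.0, 0.02),
    "ankle-on-knee-rl": (-8.0, -20.0, 0.02),
    "right-foot-move": (0.0, 5.0, 0.15),
    "left-foot-move": (0.0, -5.0, 0.15),
    "both-feet-move": (0.0, 0.0, 0.25),
    "elbows-on-legs": (3.0, 0.0, 0.02),
    "outstretched-legs": (-15.0, 0.0, 0.01),
    "stand-normal": (0.0, 0.0, 0.01),
    "weight-right": (2.0, 8.0, 0.05),
    "weight-left": (2.0, -8.0, 0.05),
    "right-shoulder-wall": (5.0, 15.0, 0.02),
    "left-shoulder-wall": (5.0, -15.0, 0.02),
    "self-paced": (0.0, 0.0, 0.0),
    "treadmill-4kmh": (0.0, 0.0, 0.0),
    "treadmill-6kmh": (0.0, 0.0, 0.0),
}

#: Step cadence (Hz) for fixed treadmill speeds.
TREADMILL_CADENCE = {"treadmill-4kmh": 1.6, "treadmill-6kmh": 2.0}

#: Earth magnetic field: downward and horizontal components (µT).
EARTH_FIELD_VERTICAL = 45.0
EARTH_FIELD_HORIZONTAL = 22.0

BATTERY_VOLTS = 4.05
BATTERY_DRAIN_V_PER_H = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Additive per-channel Gaussian noise and fidget-burst scaling.

    ``fidget_amplitude`` multiplies the burst amplitudes; setting everything
    to zero yields noiseless, burst-free physics (static accelerometer
    magnitude exactly 1 g).
    """

    sigma_accel: float = 0.02  # g
    sigma_gyro: float = 1.0  # deg/s
    sigma_mag: float = 0.5  # µT
    sigma_angle: float = 0.3  # deg
    fidget_amplitude: float = 1.0

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant posture and gait idiosyncrasies."""

    participant_id: str = "P00"
    angle_jitter: dict[Activity, float] = field(default_factory=dict, hash=False)
    cadence_hz: float = 1.8  # self-paced step frequency
    swing_amplitude_deg: float = 15.0
    roll_jitter_deg: float = 0.0


def make_profiles(n: int = 15, seed: int = 2024) -> list[ParticipantProfile]:
    """Deterministic cohort of participant profiles.

    Posture angles are jittered N(0, 3°) per activity, self-paced cadence is
    N(1.8, 0.1) Hz, gait swing N(15°, 2°).
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        jitter = {act: float(rng.normal(0.0, 3.0)) for act in Activity}
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i:02d}",
                angle_jitter=jitter,
                cadence_hz=float(rng.normal(1.8, 0.1)),
                swing_amplitude_deg=float(rng.normal(15.0, 2.0)),
                roll_jitter_deg=float(rng.normal(0.0, 4.0)),
            )
        )
    return profiles


def _gravity_device(theta_rad: np.ndarray, roll_rad: np.ndarray) -> np.ndarray:
    """Gravity direction in the device frame, shape (n, 3), unit norm."""
    return np.stack(
        [
            np.cos(theta_rad),
            np.sin(theta_rad) * np.sin(roll_rad),
            np.sin(theta_rad) * np.cos(roll_rad),
        ],
        axis=1,
    )


def _horizontal_device(theta_rad: np.ndarray, roll_rad: np.ndarray) -> np.ndarray:
    """Unit horizontal (heading-aligned) direction in the device frame."""
    return np.stack(
        [
            np.sin(theta_rad),
            -np.cos(theta_rad) * np.sin(roll_rad),
            -np.cos(theta_rad) * np.cos(roll_rad),
        ],
        axis=1,
    )


def _fidget_bursts(
    n: int, rate_hz: float, burst_rate: float, amp_scale: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Damped sinusoid bursts; returns (accel perturbation (n,3), gyro (n,3))."""
    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    duration_s = n / rate_hz
    n_bursts = rng.poisson(burst_rate * duration_s)
    for _ in range(n_bursts):
        onset = rng.uniform(0.0, duration_s)
        dur = rng.uniform(0.5, 1.5)
        freq = rng.uniform(2.0, 4.0)
        amp_a = rng.uniform(0.05, 0.15) * amp_scale
        amp_g = rng.uniform(10.0, 40.0) * amp_scale
        i0 = int(onset * rate_hz)
        i1 = min(n, int((onset + dur) * rate_hz))
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / rate_hz
        wave = np.exp(-3.0 * t / dur) * np.sin(2 * np.pi * freq * t)
        axis = rng.integers(1, 3)  # lateral or anterior
        acc[i0:i1, axis] += amp_a * wave
        gyr[i0:i1, rng.integers(0, 3)] += amp_g * wave
    return acc, gyr


def simulate_session(
    script: ProtocolScript,
    profile: ParticipantProfile | None = None,
    seed: int = 0,
    sampling_rate: float = 25.0,
    noise: NoiseModel | None = None,
) -> LabeledStream:
    """Synthesize one gap-free labeled session for a scripted protocol.

    A pure function of ``(script, profile, seed)``: identical arguments
    reproduce the stream bit for bit.
    """
    if profile is None:
        profile = ParticipantProfile()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    rate = float(sampling_rate)

    # realize rest gaps as quiet upright sitting bouts
    bouts: list[tuple[ActivityLabel, float]] = []
    rest_after = dict(script.rest_gaps)
    for k, b in enumerate(script.bouts):
        if b.duration <= 0:
            raise ValueError("bout durations must be positive")
        bouts.append((b.label, b.duration))
        if k in rest_after:
            bouts.append((ActivityLabel(Activity.SITTING, "upright"), rest_after[k]))

    seg_angle: list[np.ndarray] = []
    seg_roll: list[np.ndarray] = []
    seg_acc_extra: list[np.ndarray] = []
    seg_gyro_base: list[np.ndarray] = []
    seg_labels: list[np.ndarray] = []
    seg_variations: list[np.ndarray] = []

    prev_theta = None  # final inclination/roll of the previous bout (deg)
    prev_roll = None
    for label, duration in bouts:
        n = int(round(duration * rate))
        if n < 1:
            raise ValueError(f"bout too short for one sample: {duration}s")
        t = np.arange(n) / rate
        act = label.value
        var = label.variation
        d_theta, d_roll, fidget_rate = VARIATION_EFFECTS.get(var, (0.0, 0.0, 0.0))
        theta0 = POSTURE_ANGLES[act] + profile.angle_jitter.get(act, 0.0) + d_theta
        roll0 = d_roll + profile.roll_jitter_deg

        if act is Activity.WALKING:
            cadence = TREADMILL_CADENCE.get(var, profile.cadence_hz)
            swing = profile.swing_amplitude_deg
            phase0 = rng.uniform(0.0, 2 * np.pi)
            phase = 2 * np.pi * cadence * t + phase0
            theta = theta0 + swing * np.sin(phase)
            roll = np.full(n, roll0)
            # longitudinal impact at step frequency plus a weaker harmonic
            impact = 0.15 + 0.15 * (cadence / 2.0)
            acc_extra = np.zeros((n, 3))
            acc_extra[:, 0] = impact * np.sin(phase) + 0.4 * impact * np.sin(2 * phase)
            gyro_base = np.zeros((n, 3))
            gyro_base[:, 1] = swing * 2 * np.pi * cadence * np.cos(phase)
        else:
            theta = np.full(n, theta0)
            roll = np.full(n, roll0)
            acc_extra = np.zeros((n, 3))
            gyro_base = np.zeros((n, 3))

        # 1-2 s linear ramp from the previous posture, labeled as this bout
        if prev_theta is not None:
            trans = rng.uniform(1.0, 2.0)
            m = min(n, int(round(trans * rate)))
            w = np.linspace(0.0, 1.0, m, endpoint=False)
            theta[:m] = prev_theta + w * (theta[:m] - prev_theta)
            roll[:m] = prev_roll + w * (roll[:m] - prev_roll)
            acc_extra[:m] *= w[:, None]
            gyro_base[:m] *= w[:, None]
            # transition motion shows up in the gyro
            gyro_base[:m, 1] += np.gradient(theta[:m]) * rate
        prev_theta, prev_roll = float(theta[-1]), float(roll[-1])

        if fidget_rate > 0 and noise.fidget_amplitude > 0:
            f_acc, f_gyr = _fidget_bursts(
                n, rate, fidget_rate, noise.fidget_amplitude, rng
            )
            acc_extra += f_acc
            gyro_base += f_gyr

        seg_angle.append(theta)
        seg_roll.append(roll)
        seg_acc_extra.append(acc_extra)
        seg_gyro_base.append(gyro_base)
        seg_labels.append(np.full(n, act.value, dtype=object))
        seg_variations.append(np.full(n, var or "", dtype=object))

    theta = np.concatenate(seg_angle)
    roll = np.concatenate(seg_roll)
    acc_extra = np.concatenate(seg_acc_extra)
    gyro = np.concatenate(seg_gyro_base)
    labels = np.concatenate(seg_labels)
    variations = np.concatenate(seg_variations)
    n_total = len(theta)
    ts = np.arange(n_total) / rate

    theta_rad = np.deg2rad(theta)
    roll_rad = np.deg2rad(roll)
    accel = _gravity_device(theta_rad, roll_rad) + acc_extra
    mag = EARTH_FIELD_VERTICAL * _gravity_device(
        theta_rad, roll_rad
    ) + EARTH_FIELD_HORIZONTAL * _horizontal_device(theta_rad, roll_rad)
    angle_chan = theta.copy()

    if noise.sigma_accel > 0:
        accel = accel + rng.normal(0.0, noise.sigma_accel, accel.shape)
    if noise.sigma_gyro > 0:
        gyro = gyro + rng.normal(0.0, noise.sigma_gyro, gyro.shape)
    if noise.sigma_mag > 0:
        mag = mag + rng.normal(0.0, noise.sigma_mag, mag.shape)
    if noise.sigma_angle > 0:
        angle_chan = angle_chan + rng.normal(0.0, noise.sigma_angle, n_total)

    battery = BATTERY_VOLTS - BATTERY_DRAIN_V_PER_H * ts / 3600.0

    data = pd.DataFrame(
        {
            "timestamp": ts,
            "angle": angle_chan,
            "accel_x": accel[:, 0],
            "accel_y": accel[:, 1],
            "accel_z": accel[:, 2],
            "gyro_x": gyro[:, 0],
            "gyro_y": gyro[:, 1],
            "gyro_z": gyro[:, 2],
            "mag_x": mag[:, 0],
            "mag_y": mag[:, 1],
            "mag_z": mag[:, 2],
            "battery_voltage": battery,
            "label": labels,
            "variation": variations,
        }
    )
    return LabeledStream(
        data=data, sampling_rate=rate, participant_id=profile.participant_id
    )


def inject_packet_loss(
    stream: LabeledStream,
    loss_rate: float,
    burst_mean: float = 3.0,
    seed: int = 0,
) -> LabeledStream:
    """Drop packets in geometric-length bursts to emulate transport loss.

    Exactly ``round(n × loss_rate)`` interior packets are removed (the first
    and last packets always survive, so the session extent is preserved).
    Surviving packets keep their timestamps, channel values, and labels.
    """
    if not 0.0 <= loss_rate < 0.5:
        raise ValueError(f"loss_rate must be in [0, 0.5), got {loss_rate}")
    if loss_rate == 0.0:
        return stream
    n = len(stream)
    target = int(round(n * loss_rate))
    if target == 0:
        return stream
    if target > n - 2:
        raise ValueError("stream too short for requested loss rate")
    rng = np.random.default_rng(seed)
    drop = np.zeros(n, dtype=bool)
    removed = 0
    attempts = 0
    while removed < target and attempts < 100 * target:
        attempts += 1
        length = min(int(rng.geometric(1.0 / burst_mean)), target - removed)
        start = int(rng.integers(1, n - 1 - length)) if n - 1 - length > 1 else 1
        window = slice(start, start + length)
        if drop[window].any():
            continue
        drop[window] = True
        removed += length
    data = stream.data.loc[~drop].reset_index(drop=True)
    return stream.with_data(data)


@dataclass(frozen=True)
class ReferenceErrorModel:
    """Misclassification and onset-lag model for an imperfect reference device.

    ``confusion[a][b]`` is the per-epoch probability that true activity ``a``
    is reported as ``b``; rows may sum to less than 1 (remainder = correct).
    ``onset_lag_s`` delays every activity-change boundary by that many whole
    seconds, emulating event-detection latency.
    """

    confusion: dict[str, dict[str, float]] = field(default_factory=dict, hash=False)
    onset_lag_s: float = 0.0

    def __post_init__(self) -> None:
        for src, row in self.confusion.items():
            total = 0.0
            for dst, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"confusion[{src}][{dst}] = {p} outside [0, 1]")
                total += p
            if total > 1.0 + 1e-12:
                raise ValueError(f"confusion row {src!r} sums to {total} > 1")
        if self.onset_lag_s < 0:
            raise ValueError("onset lag must be non-negative")


def simulate_reference_device(
    stream: LabeledStream,
    error_model: ReferenceErrorModel | None = None,
    seed: int = 0,
) -> EpochSeries:
    """Derive an imperfect 1-Hz reference label series from ground truth.

    With the default zero-error model the result is exactly the 1-Hz
    majority-vote reduction of the stream's ground-truth labels.
    """
    if not stream.has_labels:
        raise ValueError("stream carries no ground-truth labels")
    if error_model is None:
        error_model = ReferenceErrorModel()
    order = tuple(a.value for a in Activity)
    series = reduce_to_epochs(
        stream.labels.to_numpy(), stream.sampling_rate, class_order=order,
        source="activpal",
    )
    labels = series.labels.copy()

    lag = int(round(error_model.onset_lag_s))
    if lag > 0:
        events = epochs_to_events(series)
        shifted = []
        for k, ev in enumerate(events):
            onset = ev.onset + lag if k > 0 else ev.onset
            end = ev.onset + ev.duration + (lag if k < len(events) - 1 else 0)
            if end > onset:
                shifted.append((onset, end - onset, ev.activity))
        from .epochs import EventRecord

        labels = events_to_epochs(
            [EventRecord(*s) for s in shifted], source="activpal"
        ).labels[: len(labels)]

    if error_model.confusion:
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=len(labels))
        out = labels.copy()
        for i, lab in enumerate(labels):
            row = error_model.confusion.get(str(lab))
            if not row:
                continue
            cum = 0.0
            for dst, p in row.items():
                cum += p
                if u[i] < cum:
                    out[i] = dst
                    break
        labels = out

    return EpochSeries(labels=labels, start_time=series.start_time, source="activpal")
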