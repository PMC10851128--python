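# Methods

`sordkit` implements the measurement-and-validation chain for a thigh-worn
Bluetooth activity tracker: raw 25-Hz inertial packets are repaired for
transmission loss, classified into postures/activities by a sliding-window
CNN+GRU, reduced to 1-second epochs, and compared against reference streams
with confusion-matrix metrics and Bland-Altman limits of agreement.  Because
no public recordings of such sessions ship with the package, a synthetic-data
module generates the study conditions end to end; everything below documents
the models, the defaults, and what the synthetic results do and do not show.

## Signal model (synthetic sessions)

A session follows a scripted protocol of activity bouts (default order:
sitting, reclining, sitting, standing, walking, standing, sitting, lying,
treadmill walking at 4 then 6 km/h; whole-second bout durations drawn
uniformly from 120–210 s, except the short self-paced over-ground walk,
45–90 s). The device frame fixes the x-axis along the thigh toward the knee
and the z-axis anterior; thigh inclination θ is measured from vertical.

* **Static postures.** The accelerometer reads gravity projected into the
  device frame, `a = [cos θ, sin θ sin φ, sin θ cos φ]` g with roll φ about
  the thigh axis — unit magnitude by construction, so noise-free static
  postures give |a| = 1 g exactly. Mean inclinations: standing 8°, walking
  12°, reclining 60° (a 135° chair), sitting 87°, lying 90°. Sitting and
  face-up lying are therefore nearly indistinguishable from a single thigh
  sensor — deliberately so, since that confusability is the known failure
  mode of thigh-worn classification and the reason the 5-class taxonomy
  performs worst on lying.
* **Gait.** During walking, θ oscillates around its mean at the step cadence
  with per-participant swing amplitude (N(15°, 2°)); the longitudinal axis
  additionally carries an impact component at the cadence and its first
  harmonic, and the pitch gyroscope carries dθ/dt. Cadences: 1.6 Hz at
  4 km/h, 2.0 Hz at 6 km/h, self-paced N(1.8, 0.1) Hz — plausible gait
  values; analyses assert only the ordering (faster belt → higher cadence).
* **Fidgeting.** Variations such as foot-moving sitting add Poisson-arriving
  damped-sinusoid bursts (0.5–1.5 s, 2–4 Hz, ≤ 0.15 g / ≤ 40 deg/s) that
  perturb the signal without changing the base label.
* **Noise.** Additive Gaussian per channel: σ_accel = 0.02 g, σ_gyro =
  1 deg/s, σ_mag = 0.5 µT, σ_angle = 0.3°. The magnetometer sees a constant
  earth field (45 µT vertical, 22 µT horizontal) rotated into the device
  frame. No posture-angle distributions or sensor-noise magnitudes are
  published for this class of device, so all signal-model constants are
  stand-ins chosen once to give class-separable but non-trivial signals.
* **Transitions.** Bout changes ramp the posture linearly over 1–2 s and are
  labeled with the destination activity, so ground-truth per-activity totals
  equal the scripted durations exactly.
* **Cohort.** 15 participant profiles with posture-angle jitter N(0, 3°),
  cadence and swing variation, mirroring a 15-subject laboratory cohort.
  The default split uses 6 training, 1 validation and 7 test participants;
  with 15 simulated, one is left unassigned, mirroring a cohort in which one
  recording is unusable.

Simulation is a pure function of (script, profile, seed).

### What the simulator does *not* emulate

Biomechanically realistic gait (no double-support phases, no inter-stride
variability beyond phase), soft-tissue artifact, device re-orientation on the
thigh over time, clock drift between devices, magnetometer disturbances from
indoor iron, and real Bluetooth transport behavior. Passing tests on this
generator therefore demonstrate that the pipeline's machinery is correct and
that the classifier can recover well-separated posture structure at realistic
sampling and noise levels — not that any specific accuracy would be achieved
on real recordings.

## Packet-loss repair

Sender-side device timestamps are authoritative. For consecutive packets
separated by ΔT at nominal rate r, the missing count is
`round(ΔT·r) − 1`, floored at 0; rounding (not truncation) absorbs clock
jitter up to half a sample period. Every missing slot is filled with the
average of the two surviving neighbors of the gap — a constant fill for
multi-sample gaps, implemented literally; linear interpolation exists behind
a flag but is off by default. Boundary gaps (no neighbor on one side) take
the single nearest neighbor. Outliers — any sample with |accel| > 8 g or
|gyro| > 2000 deg/s, both configurable — are treated as missing and refilled
by the same rule. Repair is idempotent: detect → impute → detect reports
zero missing, and surviving samples are never modified.

The packet-loss injector removes `round(n·loss_rate)` interior packets in
geometric-length bursts (mean 3), keeping the first and last packets so the
session extent is recoverable. Loss rates ≥ 0.5 void the two-sided
imputation contract and are rejected.

## Classifier

Windows of 35 consecutive samples (1.4 s at 25 Hz) are labeled by the class
of their final sample (causal convention). Default channels: accelerometer,
gyroscope and the inclination angle (7 inputs); the magnetometer adds little
for posture and is off by default. The network is

    conv1d(k=5, 32) → ReLU → maxpool2 → conv1d(k=5, 64) → ReLU → maxpool2
    → GRU(64) → softmax

implemented directly in numpy (forward, backpropagation through time, Adam)
— the model is small enough that a dedicated deep-learning runtime buys
nothing, and a pure numpy stack keeps training bit-reproducible for a fixed
seed. Training: Adam at 1e-3, batch 256, inverse-frequency class weights
(protocol bouts yield unequal class totals), per-channel z-normalization
from training data only, early stopping on validation loss (patience 5, max
30 epochs), best-validation checkpoint returned. Training windows use
stride 10 for speed; evaluation always uses stride 1. Splits are by
participant, never by window; training refuses overlapping train/validation
participants, and a label-permutation test in the suite guards against
leakage bugs.

Four taxonomies map the five base activities to classifier targets:
3-class with all sedentary postures merged (model1); sitting+reclining /
standing / walking with lying excluded (model2); sitting / standing /
walking with reclining and lying excluded (model3); and all five with only
sitting+reclining merged (model4). Excluded activities generate no training
or evaluation windows, and evaluation epochs whose true activity is excluded
are dropped pairwise from all statistics.

## Epochs, alignment, agreement

Per-sample predictions reduce to 1-second epochs by majority vote (ties →
class listed first in taxonomy order; both the rule and the tie-break are
configurable). Event files — chronological (onset, duration, activity)
episode lists at 1-second resolution, as exported by established thigh-worn
reference software — expand to the same epoch representation, with coverage
gaps marked `unknown` and excluded from comparison. Two epoch series are
aligned by the integer-second shift (±10 s default) maximizing label
agreement, ties broken toward zero; a best agreement below 0.5 raises a
warning since the series are then likely unrelated.

Agreement statistics: pooled predicted-by-actual confusion matrix (rows =
predicted), one-vs-rest accuracy/sensitivity/specificity per class
(per-class accuracies can only differ under the one-vs-rest reading), and
Bland-Altman on per-participant percent-time per class. Differences are
`reference − index`, so a positive bias means the index device
underestimates; limits of agreement are bias ± 1.96 × SD with the sample
(n−1) SD, and a class is acceptable when both limits lie within ±10
percentage points. Raw-seconds differences are also recorded. The
Bland-Altman unit of analysis is one difference per participant per class;
with a single participant the SD is undefined and the agreement block is
omitted while confusion metrics are still produced.

## Numerical and design choices

* Majority-vote epoch reduction and the agreement-maximizing alignment are
  package choices; only the rate change and the fact of synchronization are
  externally prescribed.
* 25 Hz is taken as the canonical sampling rate (it is the rate the missing-
  sample formula is stated at) and is a parameter everywhere.
* The tie-break in epoch reduction prefers the earlier class in taxonomy
  order; max-pooling ties prefer the earlier sample; both are deterministic.
* The single run seed fans out to stage seeds via
  `SeedSequence([seed, crc32(stage_name)])`, so any stage can be reproduced
  in isolation; all stage seeds stay below 2^31.
* Degenerate inputs: empty protocols, non-positive durations, loss ≥ 0.5,
  streams shorter than one window/second, all-outlier streams, single-
  participant Bland-Altman, and taxonomy classes absent from training data
  are all rejected with specific errors (or warnings where a partial result
  is well-defined).

## Problem sizes

The packaged experiment trains on 6 participants × ~24 min of 25-Hz data
(≈ 22k training windows at stride 10) and evaluates stride-1 predictions on
7 held-out participants (≈ 9.7k compared epochs per taxonomy). The
`scripts/acceptance.py` entry point reruns the full study for three
taxonomies plus a 10%-packet-loss robustness pass in a few CPU-minutes.

## Known limitations

The synthetic cohort is easier than free-living data: postures are cleanly
separated in inclination, fidgeting is mild, and there is no out-of-protocol
behavior, so held-out accuracies here (≈ 0.99 for the lying-excluded
taxonomy) sit at the optimistic end of what laboratory protocols report and
should not be read as field performance. Lying detection from a single thigh
sensor remains structurally hard (near-identical gravity projection to
sitting); the 5-class taxonomy's lying sensitivity is correspondingly the
weakest number in every run, and distinguishing lying reliably would require
a second sensor site or rotational-threshold heuristics outside this
package's scope.
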