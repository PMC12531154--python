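# Methods

## Scope and model

`footkin` is a desk-scale toolkit for marker-based foot and ankle
kinematics during treadmill walking. It covers five connected pieces:

1. detection of circular high-contrast markers in RGB-D frames and their
   back-projection to 3D through a pinhole camera model;
2. deterministic, rule-based detection of the seven stance events and the
   derived 14-class per-frame subphase labeling;
3. five clinical angle series (medial longitudinal arch, subtalar, ankle,
   tibia inclination, first metatarsophalangeal) and the 19 phase-anchored
   scalars read from them;
4. evaluation machinery for frame-level classifiers (14x14 confusion
   matrix, per-class precision/recall/F1, accuracy, macro-F1);
5. usability metrics for task-based studies (success rate, time-based
   efficiency, relative efficiency, error rate, SUS scoring and adjective
   bands).

A forward-kinematic synthetic gait generator provides the ground-truth
oracle for all of the above.

## Coordinate and unit conventions

X is mediolateral, Y vertical (up positive), Z the direction of walking
progression (anterior positive). Lengths are metres; angles are reported
in degrees, the clinical convention. Frames are 0-based and times are
`frame / fps` seconds; the sampling rate defaults to 30 fps and a
recording to 5 s (150 frames). Left and right feet are handled by
mirroring X, which makes every angle definition side-agnostic.

## Marker model

Eleven landmarks per limb: seven on the medial side (hallux DIP joint,
first metatarsal head, first metatarsal shaft midpoint, navicular
tuberosity, medial malleolus, posteromedial calcaneus, medial knee joint
line), three posterior (Achilles insertion, posterior ankle joint line
level with the malleolus, gastrocnemius musculotendinous junction) and one
on the lateral calf. Markers are modelled as 1 cm white disks on a red
background; blobs smaller than a 2 mm equivalent are rejected as
unreliable. An occluded marker is propagated downstream as explicitly
missing (NaN), never silently interpolated.

## Event rules and their tunables

Stance events are found from marker heights and the shank axis:

| event | rule |
|---|---|
| IC  | heel (CALC) height falls through the contact threshold |
| LR  | forefoot (HM) height falls through the threshold while the heel is down |
| MSt | contralateral hallux (DIP1) rises off the ground |
| TSt | signed shank inclination (MM->KNEE) crosses 0 from posterior |
| PSw | contralateral initial contact |
| HE  | argmax of MTP-1 extension strictly between PSw and ISw (earlier frame wins ties) |
| ISw | own hallux rises off the ground |

The contact threshold for a marker is its standing height — estimated as
the 10th percentile of its own height trajectory — plus 5 mm, with 3 mm of
hysteresis against chatter. Height and coordinate signals are smoothed
with a centred 3-frame moving average before crossings are located;
crossings are linearly interpolated between the bracketing frames and
rounded to the nearest frame. All thresholds are configurable through
`EventConfig`; the defaults were chosen once as values a practitioner
would consider reasonable for 30 fps treadmill data and 1-2 mm marker
noise.

Each event instant occupies exactly one frame; frames strictly between
two consecutive events carry the transition label, giving the 14-class
taxonomy (7 states + 7 transitions). Events are located independently
inside each (IC, next IC) window — every crossing is unique within a
cycle — and strict frame ordering is then enforced deterministically,
because rounding can collapse events that lie less than a frame apart
(LR and MSt are 0.6 frames apart under the default schedule). The last
cycle of a recording may end at the recording edge rather than at a
following IC. Only cycles with all seven events inside the recording are
labeled; this convention is shared by the detector and the generator's
ground truth, so the two are comparable frame by frame.

The TSt *instant* is defined as the vertical-tibia crossing. The
literature distinguishes a terminal-stance interval from this instant;
the instant convention is used throughout because it gives a unique,
reproducible anchor frame, and it keeps the subtalar series anchorable at
IC/LR/MSt/PSw while terminal stance is excluded (posterior-view subtalar
readings are unreliable there, hence `CA_TSt` is never produced).

## Angle definitions

* **MLA** — angle at the navicular. Two published endpoint conventions
  exist and they disagree: one uses the medial malleolus (MM-NV-HM), the
  other the posteromedial calcaneus (HM-NV-CALC). Both are implemented;
  `"equation"` (MM-NV-HM) is the default and `"text"` (HM-NV-CALC) is
  selectable. Larger = flatter arch.
* **CA** (subtalar) — angle at the posterior ankle joint line between the
  posterior calcaneus and the gastrocnemius MTJ; 180 deg is neutral. The
  output is tagged experimental/unvalidated in reports: posterior-view
  subtalar estimates are known to be the least accurate of the five.
* **ANK** — angle between the foot axis (CALC->HM) and the shank axis
  (MM->KNEE).
* **AI** — signed tilt of MM->KNEE from the vertical; anterior positive.
* **MTP** — angle at the metatarsal head between the shaft midpoint and
  the hallux marker; extension = 180 - MTP. The distal endpoint is
  nominally the proximal phalanx head, but the marker model places marker
  1 at the first DIP joint, so DIP1 is used; this only rescales the
  extension amplitude, not its timing.

Angles are computed in full 3D (no sagittal projection). All unsigned
angles are invariant under rigid transforms of the whole trajectory; AI
is invariant only under transforms preserving the vertical axis (its
magnitude survives yaw, its sign convention references the anterior
direction). The 19 anchored scalars are pointwise samples of the series
at the event frames: MLA at IC/LR/MSt/TSt/PSw/HE, CA at IC/LR/MSt/PSw,
ANK at IC/LR, AI at LR/MSt/TSt, MTP at TSt/PSw/HE/ISw. The "mid-loading
response" anchors sample at the foot-flat (LR) event frame, as no
numeric definition of "mid" exists. Note that because the TSt anchor *is*
the vertical crossing, `AI_TSt` is by construction near zero.

## Synthetic gait generator

The generator is forward-kinematic and fully deterministic given its
seed. Default study conditions: 30 fps, 5 s, cadence 1.0 cycle/s, stance
fraction 0.60, contralateral offset 0.5 cycle, 2 mm isotropic Gaussian
marker noise, tibia length 0.38 m. Event fractions within the cycle
default to IC 0.00, LR 0.08, MSt 0.10, TSt 0.31, PSw 0.50, HE 0.56,
ISw 0.60 — the classic ~60% stance subdivision. MSt is pinned at
ISw - 0.5 because midstance *is* contralateral toe-off under a half-cycle
offset; any other value would make the schedule internally inconsistent.
The initial phase (0.8 cycles at frame 0) is chosen so that whole cycles
fit the default 150-frame recording on both sides.

Construction principles:

* Heel, forefoot and hallux height profiles are piecewise linear with
  the contact-threshold crossings placed exactly at the scheduled event
  fractions and locally linear over about +-2 frames, so the detector's
  3-frame moving average does not displace a crossing.
* The shank is posed directly from the tibia-inclination schedule (a
  monotone cubic with its zero crossing exactly at the TSt fraction and a
  linear neighbourhood around it); the navicular is placed by an
  inscribed-angle construction so the arch angle equals the MLA schedule
  exactly; the posterior calcaneus marker is posed from the subtalar
  schedule in the plane spanned by the shank and lateral axes; the
  metatarsal-shaft marker is posed from the MTP-extension schedule. The
  ankle angle is emergent, fully determined by the foot and shank poses.
* Ground-truth angle series are computed from the noiseless markers with
  the package's own angle operators, making scheduled-vs-recovered
  comparisons well-posed; truth labels are derived from truth events via
  the same `label_subphases` used downstream.
* Occlusion is simulated by masking configurable frame spans to NaN.

What the generator does *not* emulate: soft-tissue artefact, non-periodic
stride-to-stride variability, pathological gait, marker swap/merge in the
camera image, and real depth-sensor noise. Passing tests therefore
demonstrate the correctness of the rules and geometry under controlled
conditions, not clinical accuracy on real recordings.

Rendering uses a pinhole model with defaults mimicking the physical rig
(lateral camera 52 cm from the foot, posterior camera 40 cm behind, both
40 cm high; 640x576, f = 450 px — wide enough to keep the knee marker in
frame at these close ranges). Disks are anti-aliased by analytic pixel
coverage; the depth map carries the marker's centre depth.

## Evaluation and usability conventions

* Zero-support classes get precision/recall/F1 = 0 so macro-F1 always
  divides by 14.
* Accuracy is frame-weighted (each evaluated frame counts once).
* Relative efficiency truncates (not rounds) to 3 decimals by default:
  for the worked example 0.05348 / 0.0442 = 1.20995..., truncation prints
  1.209 where rounding would print 1.210. Full precision is available via
  `mode="exact"`.
* Partial successes weigh 0.5 in the success rate but 0 in time-based
  efficiency (only full successes contribute throughput).
* Success-rate aggregation is offered both pooled and per-user-mean,
  since either convention appears in practice.
* SUS adjective bands are used exactly as printed (0-25, 25.1-51.6,
  51.7-62.6, 62.7-72.5, 72.6-84.0, 84.1-100); a score falling in a
  printed gap (e.g. 25.05) resolves to the band below. Error rate is
  reported on both the proportion and percent scales to avoid unit
  ambiguity.

## Numerical choices

Degenerate geometry (rays shorter than 1e-9 m) raises an explicit error
in scalar operators and yields NaN in vectorised series, so one missing
or collapsed marker never aborts a recording. Arc-cosine arguments are
clipped to [-1, 1]. Argmax ties resolve to the earlier frame. CSV output
uses a fixed `%.9f` format so write -> read -> write round-trips are
byte-identical.

## Problem sizes

Tests and the acceptance script use the default 150-frame recording
(9-10 cycles across both sides), 10 noiseless seeds and 20 noisy
replicates for event recovery, 100 random label streams of length 500
for the evaluation oracle, 10,000 random SUS responses, and 3 rendered
frames of 11 markers; these sizes give stable estimates of all reported
rates while keeping the whole suite fast.

## Known limitations

* The rule-based segmenter replaces a learned classifier; it requires the
  full marker set at >= 90% frame coverage per side and at least one
  complete cycle, and it assumes treadmill (stationary-mean) kinematics.
* The two camera streams are assumed pre-synchronised per frame; no
  time alignment is performed.
* The subtalar angle is computed but flagged experimental.
* The published headline classification figures and usability cohort
  aggregates cannot be reproduced here because the underlying validation
  videos and raw task logs are unpublished; the implemented machinery is
  instead verified against independent oracles and printed worked
  examples.
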