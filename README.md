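# footkin

Desk-scale foot and ankle kinematics for marker-based treadmill gait
analysis. `footkin` is aimed at clinicians and biomechanics researchers
who want reproducible, rule-based stance-phase analysis from simple
RGB-D marker recordings — without a trained keypoint model or an optical
motion-capture lab.

It provides, as a library and a `footkin` command line tool:

* **Marker detection** — circular high-contrast (white-on-red) marker
  blobs in RGB-D frames, subpixel centroids, pinhole back-projection to
  3D, and automatic anatomical labeling of an 11-marker lower-limb set.
* **Stance-subphase segmentation** — deterministic detection of the 7
  stance events per gait cycle (initial contact IC, loading response LR,
  midstance MSt, terminal stance TSt, pre-swing PSw, peak hallux
  extension HE, initial swing ISw) from heel/toe heights and tibia
  verticality, and the derived 14-class per-frame labeling
  (7 event states + 7 transitions).
* **Clinical angles** — per-frame series of the medial longitudinal arch
  (MLA), subtalar (CA), ankle (ANK), signed tibia inclination (AI) and
  first metatarsophalangeal (MTP) angles, plus the 19 phase-anchored
  scalars (e.g. `MLA_MSt`, `AI_TSt`, `MTP_HE`).
* **Classifier evaluation** — 14x14 confusion matrices, per-class
  precision/recall/F1, accuracy and macro-F1 for frame-label streams.
* **Usability metrics** — success rate, time-based efficiency, relative
  efficiency, error rate, and System Usability Scale scoring with
  adjective bands.
* **Synthetic gait generator** — a forward-kinematic bilateral marker
  simulator with exact ground-truth events, labels and angle schedules;
  it is the oracle for the entire test suite.

## The core computation

Every angle is computed by vector geometry in a fixed world frame
(X mediolateral, Y up, Z anterior). For three markers, e.g. the arch
angle at the navicular NV between the medial malleolus MM and the first
metatarsal head HM:

    v1 = MM - NV,  v2 = HM - NV,
    theta = arccos( v1 . v2 / (|v1| |v2|) )

The signed tibia inclination is the tilt of the malleolus-to-knee segment
from the vertical, positive when the knee is anterior to the ankle.
Stance events come from threshold crossings: a marker is "down" when its
height drops below its standing height (lowest decile of its trajectory)
plus 5 mm, with 3 mm hysteresis; terminal stance is the frame where the
tibia passes through vertical; hallux-extension peak is the argmax of
180 - MTP between pre-swing and toe-off. Full definitions, tunables and
design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a noiseless synthetic recording (5 s at 30 fps, cadence 1
cycle/s) and run the full pipeline:

```python
from footkin.pipeline import RunConfig, run_pipeline
from footkin.synthetic import generate

rec = generate(seed=1, noise_sd=0.0)
report = run_pipeline(RunConfig(output_dir="out", seed=1),
                      traj=rec.trajectories)
right = report["sides"]["right"]
print(right["n_cycles"], right["events"][0])
for name in ("MLA_MSt", "AI_LR", "AI_TSt", "MTP_HE"):
    print(name, round(right["anchored_mean_deg"][name], 2))
```

prints

```
5 [6, 8, 9, 15, 21, 23, 24]
MLA_MSt 145.51
AI_LR -7.75
AI_TSt -0.35
MTP_HE 150.04
```

Reading: 5 complete right-foot cycles were found; the first cycle's seven
events fall on frames 6-24. The arch is flattest near midstance
(`MLA_MSt` 145.5 deg, vs 141.2 deg at initial contact — a larger angle is
a flatter arch). The tibia is tilted 7.8 deg posteriorly at foot flat
(`AI_LR`), and is within half a degree of vertical at the terminal-stance
anchor, which is by definition the vertical crossing. At peak hallux
extension the MTP angle is 150 deg, i.e. 30 deg of extension. The same
pipeline runs on recorded data from TRC or wide-CSV trajectory files:

```sh
footkin run recording.trc --side both --out results/
footkin eval-classifier --true true_labels.csv --pred predicted.csv
footkin usability --tasks tasks.csv --sus sus.csv --expert-tbe 0.05348
```

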