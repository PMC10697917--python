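# hiptension

Analysis pipeline for intraoperative hip soft-tissue tension measured
with a force-instrumented trial femoral head, plus an independent passive
musculoskeletal prediction of the same forces.

During total hip arthroplasty, soft-tissue tension governs joint
stability, but surgeons assess it by feel. A trial head with four
internal pressure sensors turns it into a measurement: while the
anaesthetised hip is taken through passive flexion (0°→90°, three
cycles, 100 Hz), the device logs the three-dimensional contact force on
the femoral head. This package provides everything around such a device,
for biomechanics researchers and implant engineers:

* **`hiptension.frames`** — the Euler transformation chain
  `F = Ty(γ)·Tz(χ)·Tx(ε)·Tx(δ)·F′` carrying implant-frame forces into the
  pelvic frame (neck inclination δ, flexion γ, stem varus ε, anteversion
  χ), and the clinical reporting convention (positive = posterior,
  inferior, medial).
* **`hiptension.sensors`** — forward model, linear least-squares
  calibration and inverse reconstruction for the four compression-only
  sensors, plus a simulated benchtop accuracy protocol.
* **`hiptension.trials`** — cycle segmentation, the four per-cycle
  metrics (maximum force at the most-extended posture, minimum force and
  its flexion angle, force at 90°), and intra-/intersubject COV%
  statistics up to cohort level.
* **`hiptension.msk`** — a reduced passive musculoskeletal model
  (grounded pelvis, gimbal hip, pin knee, 23 hip-spanning muscle paths
  with rigid-tendon Hill passive tension, short external rotators omitted
  as in the posterolateral approach) predicting the same joint force from
  static equilibrium.
* **`hiptension.synth`** — a seeded generator producing ground-truth
  force trajectories, sensor logs and whole cohorts, so every stage is
  testable without patient data.

`docs/methods.md` describes the science and the numerical choices in
detail.

## Worked example

```python
from hiptension.sensors import CalibrationModel, NoiseSpec
from hiptension.synth import patient4_spec, generate_recording
from hiptension.trials import run_trial

cal = CalibrationModel()                      # unit gains, default layout
spec = patient4_spec(noise=NoiseSpec(), seed=5)
recording, truth = generate_recording(spec, cal)
summary = run_trial(recording, cal)
for metric, expected in truth.as_dict().items():
    print(f"{metric:18s} truth {expected:7.1f}   pipeline {summary.mean(metric):7.1f}")
```

prints

```
max_force_N        truth   186.9   pipeline   187.8
min_force_N        truth    93.0   pipeline    93.0
gamma_at_min_deg   truth    15.7   pipeline    15.7
force_at_90_N      truth   155.1   pipeline   154.2
```

— a noisy synthetic trial for a patient whose soft-tissue tension is
186.9 N in extension, dips to 93.0 N at 15.7° of flexion and rises back
to 155.1 N at 90°, pushed through sensor projection, reconstruction,
frame transformation and cycle summarisation, and recovered to within a
percent.

The same steps are available from the shell (`hiptension --help`):
`simulate`, `calibrate`, `benchmark`, `summarize`, `cohort`, `predict`,
`compare`. The numbered scripts under `analysis/` run the whole study on
synthetic data: simulate a cohort (01), benchmark the sensor head (02),
summarise the trials into a cohort table (03), sweep the passive model
(04), and compare model with measurement (05); their tables land in
`results/`.

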