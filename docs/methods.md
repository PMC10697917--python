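# Methods

## Problem

During total hip arthroplasty the surgeon judges soft-tissue tension by
feel. An instrumented trial femoral head — four single-axis pressure
sensors inside a 26 mm hemisphere on a 14 mm cube — makes that tension
measurable: as the anaesthetised hip is taken through passive flexion
(0° → 90°, three repetitions, 100 Hz logging), the sensors record the
three-dimensional contact force on the head. This package implements the
full analysis around such a device: sensor calibration and force
reconstruction, transformation of the measured force into the pelvic
frame, per-trial and cohort summary statistics, an independent passive
musculoskeletal prediction of the same quantity, and a synthetic-data
generator that lets every stage be tested without patient data.

## Coordinate frames and the transformation chain

A force `F'` measured in the implant frame O′ is carried into the pelvic
frame O by

    F = Ty(γ) · Tz(χ) · Tx(ε) · Tx(δ) · F′

with the stem neck inclination δ (130° for the implant modelled here,
expressed in the implant frame and therefore applied innermost), stem
varus ε, stem anteversion χ, and the time-varying hip flexion γ. Angles
are degrees at every interface and radians internally. `Tx/Ty/Tz` are the
standard right-handed elementary rotations.

The chain fixes the pelvic axis conventions: since `Ty(γ)` is the flexion
rotation, Y must be the mediolateral axis — the component a flexion sweep
leaves unchanged, which is exactly the component observed to stay roughly
constant during trials — with X anterior and Z the longitudinal axis.
Reported clinical components (positive = posterior, inferior, medial) are
`posterior = −Fx`, `inferior = +Fz`, `medial = −Fy` for a right hip (the
side flips only the mediolateral sign). The head frame has Z′ along the
taper axis (sensor #1), with the sensed faces on +Z′, −Y′ and an opposed
±X′ pair; X′ is the one axis whose sign reverses between extension and
flexion, which is why it needs the opposed pair, while the compressive
joint load keeps the Z′ and −Y′ loads one-signed throughout the sweep
(verified numerically across the admissible ε/χ range).

## Sensor model, calibration, reconstruction

Each channel is affine and compression-only:

    s_i = max(0, n_i · F′) / gain_i + offset_i + noise

Calibration fits (gain, offset) per channel by ordinary least squares of
signal against applied normal load; channels never excited by the supplied
loads are flagged rather than guessed. Reconstruction de-offsets and
rescales to normal loads, folds each opposed pair into one signed load
(their rectifications are mutually exclusive), and solves the linear
system by least squares. The noiseless project→reconstruct round trip is
exact to 1e−9 N for loads in the sensed cone.

The default noise model is multiplicative Gaussian (σ = 1 % of reading)
plus additive Gaussian (σ = 0.5 N equivalent), both seedable. On the
benchtop protocol grid (polar angle θ 30–90°, azimuth φ 0–45° measured
from +X′ toward −Y′, 15° increments, three repetitions, magnitudes
50–800 N bracketing the intraoperative range) this yields a mean absolute
magnitude error around 0.7 % and a mean absolute direction error around
0.4°, inside the 2.87 % / 1.44° reported for the physical device's
benchtop calibration — the noise defaults were chosen to be consistent
with those bounds, not to reproduce them exactly.

## Trial statistics

Cycle segmentation takes maximal non-decreasing sweeps of the smoothed
flexion trace from below 5° to above 85° (centred moving average, 0.25 s
window, odd-reflection padding so linear trends are not flattened at the
boundaries). Per cycle:

* **maximum force** — resultant at the most-extended sample (not the
  global maximum; the two coincide for U-shaped profiles),
* **minimum force** and **its flexion angle**,
* **force at 90°** — linear interpolation in γ, falling back to the last
  sample when the sweep stops between 85° and 90°.

The force valley is shallow (curvature ~0.01 N/deg² on its flexion side),
so a pointwise argmin wanders by several degrees under Newton-level noise.
When a cycle is clearly U-shaped (both ends exceed the discrete minimum by
more than 3 estimated noise SDs and 1 % of the minimum), the minimum and
its angle are instead taken from a least-squares fit of a three-anchor
shape-preserving monotone cubic (PCHIP) resultant profile; this estimator
is exact on noiseless quadratic and PCHIP profiles and has ~0.03°
dispersion at default noise. Flat or monotone cycles keep the discrete
minimum, with ties resolved to the earliest sample.

COV% = 100 · sd / mean with the sample (n−1) standard deviation — the
published intersubject values (16.5 %, 40.2 %) match n−1 and not n.
Cohort numbers are means of patient means; the intersubject COV is the
COV across patient means; the mean intrasubject COV averages per-patient
COVs, skipping patients with fewer than two valid cycles (such patients
and corrupted cycles are flagged, never silently dropped). Feeding the
published per-patient means through this aggregator reproduces the
published cohort means (418.7 N maximum force, 32.8° angle at minimum)
exactly; the published maximum-force intersubject COV and 90°-force
cohort mean are not reproducible from the printed per-patient means and
are treated as inconsistencies of the source table, not targets.

## Passive musculoskeletal model

A reduced rigid-body chain: pelvis fixed to ground, femur on a 3-DOF
gimbal hip, lumped shank+foot on a 1-DOF knee pin, with knee flexion
coupled 1:1 to hip flexion by default (both joints are moved together
during trialing; the coupling is configurable). Supine gravity acts along
−X (posteriorly); segment masses are standard fractions of body mass
(thigh 0.100, shank 0.0465, foot 0.0145), and inertial forces are
excluded because the motion is slow.

Muscles are straight polylines between body-fixed attachment points (via
points act as frictionless deviators) carrying rigid-tendon Hill passive
tension only (zero excitation under anaesthesia):

    F = F_iso · (exp(k_pe (l̃−1)/ε₀) − 1) / (exp(k_pe) − 1)   for l̃ > 1

with l̃ = (L − l_ts)/l_opt, k_pe = 4, ε₀ = 0.6. The roster covers the
hip-spanning musculature as 23 compartment paths (three-compartment
glutei, two-compartment adductor magnus); the short external rotators are
omitted because the posterolateral approach divides them. The attachment
geometry is a synthetic reduced-model parameter set authored for this
package — anatomically plausible coordinates chosen so that the
antagonistic stretch pattern holds: hamstring and gluteus maximus paths
lengthen monotonically with coupled flexion, iliopsoas and rectus femoris
lengthen with extension (checked on a 1° grid). Two gluteal compartments
carry a femoral via point representing wrap over the trochanter, without
which a straight chord shortens unphysically in deep flexion.

Fiber and tendon lengths are derived from the geometry itself so the
parameter set is internally consistent: each muscle reaches optimal fiber
length at its engagement angle of the coupled sweep (flexor group 25–40°,
extensor group 35–50°) and 30 % fiber strain at whichever end of the
sweep stretches it; the near-isometric abductors instead carry a slight
constant pretension (l̃ ≈ 1.08 at mid-sweep) supplying the small medial
component. Maximal isometric forces are conventional adult values. The
frozen parameter table ships as `data/muscles_generic.csv` and is
regenerated bit-identically by `generic_model()`.

Scaling to a patient multiplies all lengths (segments, attachments,
l_opt, l_ts) by the height ratio and masses by the mass ratio; F_iso is
unchanged. Because per-muscle stiffness cannot be personalised from
intraoperative data, a single global `stiffness_scale` multiplier is
exposed instead. The default target is the 151 cm / 58 kg patient of the
measured series.

Statics: the joint reaction on the femur is the negation of the summed
muscle pulls (each directed along the path segment adjacent to the
pelvis-side attachment) plus limb weight; the residual of this balance is
checked to < 1e−9 N at every angle. The *reported* force is the
acetabular load — the negated reaction, i.e. the force the head transmits
to the pelvis, which is the quantity the instrumented head's convention
describes.

With the default model the resultant is U-shaped (≈540 N at 0°, minimum
≈106 N at 35°, ≈678 N at 90°), the minimum falls inside the measured
10–50° window, the posterior component rises essentially monotonically
with flexion (Spearman ρ > 0.99) and the superior component falls to
under a tenth of its extension value. Model magnitudes are larger than
the measured series because passive stiffness is generic, as expected for
an unpersonalised model; only pattern-level agreement is claimed.

## Synthetic-data generator

The generator works backwards through the measurement chain. A virtual
patient is four resultant anchors — force at 0°, minimum force and its
angle, force at 90° (defaults: the 186.9 / 93.0 / 15.7° / 155.1 N of the
smallest measured patient) — interpolated by a shape-preserving monotone
cubic, so the resultant passes through the anchors exactly and never
undershoots the minimum. The direction splits into a constant mediolateral
component (0.45 × minimum force) and an in-plane angle linear in γ,
parameterised by two crossover angles: antero-posterior at 10°,
supero-inferior at 90°. These defaults were fixed once so that, at the
patient-4 anchors, the reported posterior and inferior components are
monotone in γ and the implied head-frame force stays inside the sensed
cone; the source reports component behaviour only graphically, so the
split is validated qualitatively, not numerically.

Each cycle is a triangular 0→90→0 flexion ramp at 15 s per half-sweep
(slow passive motion) sampled at 100 Hz; the pelvic truth is carried into
the head frame by the inverse chain, projected onto the sensors with the
seeded noise model, and logged. Ground-truth cycle metrics accompany every
recording. Cohorts draw anchors log-normally (forces are positive with a
large right-skewed spread; the defaults use the measured cohort means and
intersubject CVs: 418.7 N/0.583, 120 N/0.165, 32.8°/0.402, 204.5 N/0.242),
clipping the minimum below the endpoint forces.

What the generator does **not** emulate: sensor drift, temperature
response and hysteresis; contact-patch mechanics on the sphere; flexion
away from the sagittal plane; angle-measurement error in γ itself; and
any dislocation/rim-loading events. Passing round-trip tests therefore
demonstrates internal consistency of the pipeline, not robustness to
those real-world effects.

## Problem sizes and numerics

Recordings are three 30 s cycles at 100 Hz (9001 samples); the benchtop
grid is 360 loads; model sweeps use a 1° grid (91 poses × 23 paths).
Rotation matrices are checked orthonormal to 1e−12, the chain against an
independently composed matrix product to 1e−9 N over 1000 random draws,
force-balance residuals to 1e−9 N. Degenerate inputs are explicit: a
constant flexion trace segments to no cycles; an all-at-offset sample
reconstructs to zero force with a no-load flag; a cycle shorter than 10
samples, or not reaching 85°, is rejected; rank-deficient calibration
designs are refused with a channel-level diagnostic.

## Known limitations

* The model's superior component is not monotone: it bumps upward between
  roughly 40° and 70° as the stretching extensors' pull direction still
  has a superior fraction before rotating posterior. The measured pattern
  direction (superior falls, posterior rises from extension to deep
  flexion) holds at the endpoints and in trend.
* Straight-line muscle paths understate moment arms where real muscles
  wrap; only two gluteal via points correct for this.
* The component split of the generator and the model's absolute
  magnitudes are qualitative by construction; no figure-level numeric
  agreement is claimed.
* The two sensed one-sided axes assume a compressive joint load; a
  distractive load (head pulled out of the cup) would be invisible to the
  modelled device, as to the physical one.
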