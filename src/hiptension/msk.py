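"""Passive musculoskeletal model of the hip for anaesthetised ROM trials.

Predicts the hip joint force produced purely by passive muscle stretch and
limb weight while the surgeon flexes the hip (and knee) from 0 to 90
degrees.  The model is deliberately reduced: a pelvis fixed to ground, a
femur on a 3-DOF gimbal hip, and a lumped shank+foot on a 1-DOF knee pin,
with the hip-spanning musculature (16 muscles, modelled as 23 compartment
paths) as straight polylines between body-fixed attachment points.  The short external rotators are absent, mirroring the
posterolateral surgical approach in which they are divided.

Muscles carry force through a rigid-tendon Hill passive element only
(excitation is zero under anaesthesia): with path length L, tendon slack
length l_ts and optimal fiber length l_opt, the normalised fiber length is
l~ = (L - l_ts)/l_opt and the tension

    F = F_iso * (exp(k_pe (l~ - 1) / eps0) - 1) / (exp(k_pe) - 1),  l~ > 1

zero below optimal length.  k_pe = 4 and eps0 = 0.6 are the conventional
passive shape constants (force reaches F_iso at 60% fiber strain).

Statics: the joint reaction on the femur equals minus the sum of muscle
pulls on the femur and the lower-limb weight (inertia neglected for slow
passive motion).  The acetabular load - the force the head transmits to
the pelvis, the quantity measured by an instrumented head - is its
negation, and is what the reported (posterior, inferior, medial)
components describe.

Coordinates follow the pelvic frame of :mod:`hiptension.frames` for a
right hip: X anterior, Y lateral, Z inferior (distal), origin at the hip
center; the patient lies supine so gravity acts along -X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import Frame, ForceVector, Side, rot_y, to_reported, ReportedForce

__all__ = [
    "MuscleParam",
    "JointState",
    "Segment",
    "MskModel",
    "PassiveSweepResult",
    "generic_model",
    "scale_model",
    "muscle_path_length",
    "passive_fiber_force",
    "hip_reaction",
    "sweep_flexion",
    "patient4_model",
    "load_muscle_csv",
    "save_muscle_csv",
]

G_ACCEL = 9.81
REF_HEIGHT_CM = 170.0
REF_MASS_KG = 70.0

# segment mass fractions of whole-body mass (standard anthropometric
# coefficients) and center-of-mass position as a fraction of segment length
MASS_FRACTIONS = {"femur": 0.100, "shank": 0.0465, "foot": 0.0145}
THIGH_LEN_M = 0.410
SHANK_LEN_M = 0.430
COM_FRACTION = 0.433

K_PE_DEFAULT = 4.0
EPS0_DEFAULT = 0.6


@dataclass(frozen=True)
class JointState:
    """Hip gimbal + knee pin configuration, degrees.

    Passive trials hold adduction and rotation at zero; they are retained
    so the kinematic chain is explicit about its degrees of freedom.
    """

    hip_flexion_deg: float
    hip_adduction_deg: float = 0.0
    hip_rotation_deg: float = 0.0
    knee_flexion_deg: float = 0.0

    def __post_init__(self) -> None:
        if not -10.0 <= self.hip_flexion_deg <= 120.0:
            raise ValueError("hip flexion outside [-10, 120] degrees")


@dataclass
class Segment:
    name: str
    mass_kg: float
    com_local: np.ndarray  # in the segment frame

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"segment {self.name}: mass must be positive")
        self.com_local = np.asarray(self.com_local, dtype=float).reshape(3)


@dataclass
class MuscleParam:
    """One muscle path: attachment polyline plus passive-force parameters.

    ``points`` is an ordered list of (segment, xyz) pairs from the
    pelvis-side origin to the distal insertion; via points act as
    frictionless straight-line deviators.
    """

    name: str
    points: list[tuple[str, np.ndarray]]
    f_iso_max: float
    l_opt: float
    l_ts: float
    k_pe: float = K_PE_DEFAULT
    eps0: float = EPS0_DEFAULT

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"{self.name}: polyline needs >= 2 points")
        self.points = [(seg, np.asarray(p, dtype=float).reshape(3))
                       for seg, p in self.points]
        if self.points[0][0] != "pelvis":
            raise ValueError(f"{self.name}: path must originate on the pelvis")
        if not (self.f_iso_max > 0 and self.l_opt > 0 and self.l_ts > 0):
            raise ValueError(f"{self.name}: force/length parameters must be positive")


@dataclass
class MskModel:
    """Scaled rigid-segment model: pelvis (grounded), femur, shank+foot."""

    segments: dict[str, Segment]
    muscles: list[MuscleParam]
    thigh_len: float = THIGH_LEN_M
    shank_len: float = SHANK_LEN_M
    height_cm: float = REF_HEIGHT_CM
    mass_kg: float = REF_MASS_KG
    side: Side = Side.RIGHT
    stiffness_scale: float = 1.0  # global passive-stiffness multiplier

    def limb_weight(self) -> np.ndarray:
        """Total lower-limb gravity force vector (supine: along -X)."""
        m = sum(s.mass_kg for s in self.segments.values())
        return np.array([-m * G_ACCEL, 0.0, 0.0])


def _segment_transforms(model: MskModel, state: JointState
                        ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(rotation, origin) carrying each segment frame to the ground frame.

    Flexion is a positive rotation about the mediolateral Y axis; knee
    flexion swings the shank posteriorly relative to the femur.
    """
    r_hip = (rot_y(state.hip_flexion_deg)
             @ _rot_x_deg(state.hip_adduction_deg)
             @ _rot_z_deg(state.hip_rotation_deg))
    knee_local = np.array([0.0, 0.0, model.thigh_len])
    r_knee = r_hip @ rot_y(-state.knee_flexion_deg)
    return {
        "pelvis": (np.eye(3), np.zeros(3)),
        "femur": (r_hip, np.zeros(3)),
        "shank": (r_knee, r_hip @ knee_local),
    }


def _rot_x_deg(a: float) -> np.ndarray:
    from .frames import rot_x
    return rot_x(a)


def _rot_z_deg(a: float) -> np.ndarray:
    from .frames import rot_z
    return rot_z(a)


def _world_points(m: MuscleParam, tf) -> np.ndarray:
    pts = []
    for seg, p in m.points:
        seg = "shank" if seg in ("tibia", "shank", "foot") else seg
        r, o = tf[seg]
        pts.append(r @ p + o)
    return np.array(pts)


def muscle_path_length(m: MuscleParam, state: JointState,
                       model: MskModel | None = None) -> float:
    """Polyline path length through the current joint poses, meters."""
    model = model or generic_model()
    tf = _segment_transforms(model, state)
    pts = _world_points(m, tf)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def passive_fiber_force(m: MuscleParam, path_length: float,
                        stiffness_scale: float = 1.0) -> tuple[float, bool]:
    """Rigid-tendon passive tension at the given path length.

    Returns (force_N, slack_flag); slack covers both a buckled fiber
    (path shorter than the tendon) and lengths at or below optimal.
    """
    if path_length <= 0:
        raise ValueError("path length must be positive")
    l_f = path_length - m.l_ts
    if l_f <= 0:
        return 0.0, True
    l_norm = l_f / m.l_opt
    if l_norm <= 1.0:
        return 0.0, True
    f = m.f_iso_max * math.expm1(m.k_pe * (l_norm - 1.0) / m.eps0) / math.expm1(m.k_pe)
    return stiffness_scale * f, False


def hip_reaction(model: MskModel, state: JointState,
                 gravity: bool = True) -> tuple[np.ndarray, dict]:
    """Static joint reaction on the femur at the hip, pelvic frame, N.

    reaction = -(sum of muscle pulls on the femur + limb weight).  Each
    muscle pull acts along the path segment adjacent to its pelvis-side
    attachment, drawing the femur toward the pelvis.  Returns the
    reaction and a per-muscle force breakdown.
    """
    tf = _segment_transforms(model, state)
    total = np.zeros(3)
    detail: dict[str, dict] = {}
    for m in model.muscles:
        pts = _world_points(m, tf)
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        force, slack = passive_fiber_force(m, length, model.stiffness_scale)
        seg_vec = pts[0] - pts[1]  # toward the pelvis-side attachment
        norm = np.linalg.norm(seg_vec)
        unit = seg_vec / norm if norm > 0 else np.zeros(3)
        vec = force * unit
        total += vec
        detail[m.name] = {"length_m": length, "force_N": force,
                          "slack": slack, "vector_N": vec}
    weight = model.limb_weight() if gravity else np.zeros(3)
    reaction = -(total + weight)
    return reaction, {"muscles": detail, "gravity_N": weight,
                      "muscle_sum_N": total}


@dataclass
class PassiveSweepResult:
    """Joint forces over a flexion sweep with knee coupling."""

    gamma_deg: np.ndarray
    reaction: np.ndarray           # (n, 3) reaction on the femur, pelvic frame
    reported: list[ReportedForce]  # acetabular load (-reaction), clinical axes
    muscle_forces: pd.DataFrame    # per-muscle tension magnitudes per gamma
    residual: np.ndarray           # force-balance residual per gamma

    @property
    def resultant_N(self) -> np.ndarray:
        return np.linalg.norm(self.reaction, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gamma_deg": self.gamma_deg,
            "posterior_N": [r.posterior for r in self.reported],
            "inferior_N": [r.inferior for r in self.reported],
            "medial_N": [r.medial for r in self.reported],
            "resultant_N": self.resultant_N,
        })


def sweep_flexion(model: MskModel, gamma_grid=None, gravity: bool = True,
                  knee_coupling: float = 1.0) -> PassiveSweepResult:
    """Quasi-static sweep of hip flexion with the knee flexed in tandem.

    ``knee_coupling`` sets knee flexion as a multiple of hip flexion
    (1.0: both move together through 0-90, as during passive trialing).
    """
    if gamma_grid is None:
        gamma_grid = np.arange(0.0, 90.5, 1.0)
    g = np.asarray(gamma_grid, dtype=float)
    reactions, reported, resid, rows = [], [], [], []
    for gi in g:
        state = JointState(hip_flexion_deg=float(gi),
                           knee_flexion_deg=float(knee_coupling * gi))
        r, detail = hip_reaction(model, state, gravity=gravity)
        reactions.append(r)
        resid.append(np.linalg.norm(r + detail["muscle_sum_N"] + detail["gravity_N"]))
        acetab = ForceVector.from_array(-r, Frame.PELVIS_O)
        reported.append(to_reported(acetab, model.side))
        rows.append({"gamma_deg": gi, **{k: v["force_N"]
                                         for k, v in detail["muscles"].items()}})
    return PassiveSweepResult(g, np.array(reactions), reported,
                              pd.DataFrame(rows), np.array(resid))


# ---------------------------------------------------------------------------
# Generic model construction
#
# Attachment coordinates (meters, reference stature 170 cm) are a synthetic
# reduced-model parameter set authored for this package: anatomically
# plausible straight-line paths that reproduce the qualitative passive
# behaviour of the hip (antagonistic stretch of flexors in extension and
# extensors in flexion).  Each entry below gives the polyline and the
# engagement angle gamma_on at which the muscle reaches optimal fiber
# length during the coupled hip+knee sweep; tendon slack lengths are
# derived from that angle, which is how the U-shaped passive force profile
# is encoded.

_ROSTER = [
    # name, group, f_iso, gamma_on, points: (segment, x, y, z)
    ("glut_max1", "extensor", 573.0, 35.0,
     [("pelvis", -0.090, 0.030, -0.075), ("femur", -0.035, 0.030, 0.010),
      ("femur", -0.025, 0.030, 0.075)]),
    ("glut_max2", "extensor", 819.0, 40.0,
     [("pelvis", -0.095, 0.015, -0.028), ("femur", -0.036, 0.025, 0.015),
      ("femur", -0.022, 0.025, 0.085)]),
    ("glut_max3", "extensor", 552.0, 45.0,
     [("pelvis", -0.098, 0.005, 0.005), ("femur", -0.018, 0.020, 0.110)]),
    ("glut_med1", "abductor", 819.0, None,
     [("pelvis", 0.010, 0.055, -0.055), ("femur", -0.005, 0.050, 0.015)]),
    ("glut_med2", "abductor", 573.0, None,
     [("pelvis", -0.015, 0.050, -0.055), ("femur", -0.008, 0.048, 0.018)]),
    ("glut_med3", "abductor", 653.0, None,
     [("pelvis", -0.035, 0.040, -0.050), ("femur", -0.010, 0.046, 0.020)]),
    ("glut_min1", "abductor", 270.0, None,
     [("pelvis", 0.005, 0.045, -0.040), ("femur", -0.003, 0.044, 0.012)]),
    ("glut_min2", "abductor", 285.0, None,
     [("pelvis", -0.010, 0.042, -0.040), ("femur", -0.005, 0.043, 0.014)]),
    ("glut_min3", "abductor", 323.0, None,
     [("pelvis", -0.025, 0.038, -0.038), ("femur", -0.007, 0.042, 0.016)]),
    ("iliacus", "flexor", 1073.0, 30.0,
     [("pelvis", 0.048, 0.020, -0.055), ("pelvis", 0.035, 0.005, 0.010),
      ("femur", -0.028, -0.012, 0.060)]),
    ("psoas", "flexor", 1113.0, 35.0,
     [("pelvis", 0.042, -0.010, -0.090), ("pelvis", 0.033, 0.002, 0.012),
      ("femur", -0.030, -0.013, 0.065)]),
    ("rect_fem", "flexor", 779.0, 25.0,
     [("pelvis", 0.045, 0.008, -0.020), ("shank", 0.040, 0.000, 0.075)]),
    ("sartorius", "flexor", 156.0, 25.0,
     [("pelvis", 0.038, 0.025, -0.030), ("shank", 0.008, -0.030, 0.090)]),
    ("tfl", "flexor", 233.0, 25.0,
     [("pelvis", 0.032, 0.042, -0.030), ("femur", 0.005, 0.045, 0.080)]),
    ("pectineus", "flexor", 177.0, 30.0,
     [("pelvis", 0.022, -0.040, 0.000), ("femur", -0.012, -0.010, 0.095)]),
    ("add_longus", "flexor", 627.0, 35.0,
     [("pelvis", 0.025, -0.048, 0.010), ("femur", 0.005, -0.015, 0.200)]),
    ("add_brevis", "flexor", 429.0, 25.0,
     [("pelvis", 0.012, -0.050, 0.020), ("femur", -0.004, -0.012, 0.120)]),
    ("add_mag_mid", "extensor", 381.0, 50.0,
     [("pelvis", -0.060, -0.045, 0.038), ("femur", 0.004, -0.018, 0.230)]),
    ("add_mag_isch", "extensor", 343.0, 45.0,
     [("pelvis", -0.080, -0.030, 0.050), ("femur", 0.006, -0.020, 0.360)]),
    ("gracilis", "flexor", 108.0, 30.0,
     [("pelvis", 0.008, -0.052, 0.030), ("shank", 0.005, -0.032, 0.095)]),
    ("semimem", "extensor", 1030.0, 40.0,
     [("pelvis", -0.085, -0.022, 0.055), ("shank", -0.024, -0.019, 0.050)]),
    ("semiten", "extensor", 328.0, 40.0,
     [("pelvis", -0.088, -0.026, 0.060), ("shank", -0.008, -0.029, 0.055)]),
    ("bifem_lh", "extensor", 717.0, 45.0,
     [("pelvis", -0.086, -0.016, 0.058), ("shank", -0.022, 0.030, 0.048)]),
]
# roster has 23 entries; the three gluteus maximus / medius / minimus
# compartments count as one muscle each in the 20-muscle tally

_ABDUCTOR_PRETENSION_NORM = 1.08   # slight stretch at mid-sweep
_ABDUCTOR_REF_GAMMA = 45.0
_END_RANGE_STRAIN = 0.30  # fiber strain reached at the taut end of the sweep


def _bare_model(side: Side = Side.RIGHT) -> MskModel:
    segs = {
        "femur": Segment("femur", MASS_FRACTIONS["femur"] * REF_MASS_KG,
                         [0.0, 0.0, COM_FRACTION * THIGH_LEN_M]),
        "shank": Segment("shank",
                         (MASS_FRACTIONS["shank"] + MASS_FRACTIONS["foot"]) * REF_MASS_KG,
                         [0.0, 0.0, COM_FRACTION * SHANK_LEN_M]),
    }
    return MskModel(segments=segs, muscles=[], side=side)


def generic_model(side: Side = Side.RIGHT,
                  stiffness_scale: float = 1.0) -> MskModel:
    """The unscaled 20-muscle generic model at reference stature.

    Fiber and tendon lengths are derived from the path geometry itself so
    the parameter set is internally consistent: each muscle reaches
    optimal fiber length at its engagement angle gamma_on of the coupled
    hip+knee sweep and a fixed end-range fiber strain at whichever end of
    the sweep stretches it; the abductor compartments, whose length
    hardly changes with sagittal motion, carry a slight constant
    pretension instead.
    """
    model = _bare_model(side)
    model.stiffness_scale = stiffness_scale
    sweep = [JointState(hip_flexion_deg=float(g), knee_flexion_deg=float(g))
             for g in np.linspace(0.0, 90.0, 31)]
    for name, group, f_iso, gamma_on, raw_pts in _ROSTER:
        pts = [(seg, np.array(xyz, dtype=float)) for seg, *xyz in raw_pts]
        m = MuscleParam(name=name, points=pts, f_iso_max=f_iso,
                        l_opt=1.0, l_ts=1.0)
        lengths = np.array([muscle_path_length(m, s, model) for s in sweep])
        if gamma_on is None:
            l_ref = float(np.interp(_ABDUCTOR_REF_GAMMA, np.linspace(0, 90, 31),
                                    lengths))
            l_opt = 0.5 * l_ref
            l_ts = l_ref - _ABDUCTOR_PRETENSION_NORM * l_opt
        else:
            l_on = float(np.interp(gamma_on, np.linspace(0, 90, 31), lengths))
            l_end = float(lengths.max())  # the taut end of the sweep
            l_opt = (l_end - l_on) / _END_RANGE_STRAIN
            l_opt = min(l_opt, 0.8 * l_on)
            l_ts = l_on - l_opt
        if l_ts <= 0:
            raise RuntimeError(f"{name}: derived tendon slack length <= 0")
        m.l_opt, m.l_ts = l_opt, l_ts
        model.muscles.append(m)
    return model


def scale_model(generic: MskModel, height_cm: float, mass_kg: float) -> MskModel:
    """Scale the generic model to a patient's stature and mass.

    Lengths (segment lengths, attachment coordinates, optimal fiber and
    tendon slack lengths) scale with the height ratio; segment masses with
    the mass ratio; maximal isometric forces are left unchanged.
    """
    if height_cm <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    s_len = height_cm / generic.height_cm
    s_mass = mass_kg / generic.mass_kg
    segments = {
        name: Segment(seg.name, seg.mass_kg * s_mass, seg.com_local * s_len)
        for name, seg in generic.segments.items()
    }
    muscles = [
        MuscleParam(m.name, [(seg, p * s_len) for seg, p in m.points],
                    m.f_iso_max, m.l_opt * s_len, m.l_ts * s_len, m.k_pe, m.eps0)
        for m in generic.muscles
    ]
    return MskModel(segments=segments, muscles=muscles,
                    thigh_len=generic.thigh_len * s_len,
                    shank_len=generic.shank_len * s_len,
                    height_cm=height_cm, mass_kg=mass_kg, side=generic.side,
                    stiffness_scale=generic.stiffness_scale)


def patient4_model(stiffness_scale: float = 1.0) -> MskModel:
    """The default modelling target: the 151 cm / 58 kg patient."""
    return scale_model(generic_model(stiffness_scale=stiffness_scale), 151.0, 58.0)


# --------------------------------------------------------------------------
# Fixture CSV round trip

def save_muscle_csv(model: MskModel, path: str | Path) -> None:
    rows = []
    for m in model.muscles:
        seg_o, p_o = m.points[0]
        seg_i, p_i = m.points[-1]
        via = ";".join(f"{seg}:{p[0]:.6f}:{p[1]:.6f}:{p[2]:.6f}"
                       for seg, p in m.points[1:-1])
        rows.append({
            "name": m.name, "segment_origin": seg_o,
            "ox": p_o[0], "oy": p_o[1], "oz": p_o[2], "via": via,
            "segment_insertion": seg_i, "ix": p_i[0], "iy": p_i[1], "iz": p_i[2],
            "f_iso_max": m.f_iso_max, "l_opt": m.l_opt, "l_ts": m.l_ts,
            "k_pe": m.k_pe, "eps0": m.eps0,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")


def load_muscle_csv(path: str | Path | None = None,
                    side: Side = Side.RIGHT) -> MskModel:
    """Build a model from a muscle fixture CSV (default: the shipped one)."""
    if path is None:
        ref = resources.files("hiptension.data") / "muscles_generic.csv"
        df = pd.read_csv(ref.open())
    else:
        df = pd.read_csv(path)
    model = _bare_model(side)
    for _, row in df.iterrows():
        pts = [(row["segment_origin"],
                np.array([row["ox"], row["oy"], row["oz"]]))]
        if isinstance(row.get("via"), str) and row["via"]:
            for chunk in row["via"].split(";"):
                seg, x, y, z = chunk.split(":")
                pts.append((seg, np.array([float(x), float(y), float(z)])))
        pts.append((row["segment_insertion"],
                    np.array([row["ix"], row["iy"], row["iz"]])))
        model.muscles.append(MuscleParam(
            row["name"], pts, row["f_iso_max"], row["l_opt"], row["l_ts"],
            row.get("k_pe", K_PE_DEFAULT), row.get("eps0", EPS0_DEFAULT)))
    return model
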