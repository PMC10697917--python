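"""Coordinate frames and the head-to-pelvis force transformation.

Two frames matter for an instrumented femoral trial head:

``HEAD_OPRIME``
    The implant-fixed frame O' of the sensor head.  Z' runs from the
    hemispherical articular surface toward the stem taper (sensor #1 sits
    on that axis), X' and Y' lie on the faces of the cube that carries the
    remaining sensors.
``PELVIS_O``
    The body-fixed pelvic frame O, with X pointing anteriorly.  The full
    axis triad is a package convention (see :func:`to_reported`): Y is the
    mediolateral axis (lateral for a right hip) and Z the longitudinal
    axis, oriented so that hip flexion is a positive rotation about Y.

A force measured in O' is carried into O by the four-angle Euler chain

    F = Ty(gamma) . Tz(chi) . Tx(epsilon) . Tx(delta) . F'

where delta is the stem neck inclination (constant, 130 deg for the
implant modelled here), gamma the hip flexion angle, epsilon the stem
varus angle and chi the stem anteversion, with delta applied innermost
(it is the only angle expressed in the implant frame).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Frame",
    "Side",
    "ForceVector",
    "PatientGeometry",
    "ReportedForce",
    "rot_x",
    "rot_y",
    "rot_z",
    "chain_matrix",
    "head_to_pelvis",
    "pelvis_to_head",
    "to_reported",
]


class Frame(enum.Enum):
    """Tag identifying which coordinate system a force lives in."""

    HEAD_OPRIME = "head_oprime"
    PELVIS_O = "pelvis_o"


class Side(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


def _check_angle(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def rot_x(alpha_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the x axis (degrees)."""
    a = math.radians(_check_angle("alpha_deg", alpha_deg))
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(alpha_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the y axis (degrees)."""
    a = math.radians(_check_angle("alpha_deg", alpha_deg))
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(alpha_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the z axis (degrees)."""
    a = math.radians(_check_angle("alpha_deg", alpha_deg))
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class ForceVector:
    """A 3D force in Newtons, tagged with the frame its components use."""

    fx: float
    fy: float
    fz: float
    frame: Frame

    def __post_init__(self) -> None:
        for name in ("fx", "fy", "fz"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"ForceVector.{name} must be finite, got {v!r}")

    @classmethod
    def from_array(cls, arr, frame: Frame) -> "ForceVector":
        a = np.asarray(arr, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)

    def as_array(self) -> np.ndarray:
        return np.array([self.fx, self.fy, self.fz])

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.as_array()))


@dataclass
class PatientGeometry:
    """Per-patient implant/limb angles entering the transformation chain.

    gamma (hip flexion) is time-varying and supplied per sample, so it is
    not stored here.
    """

    delta_deg: float = 130.0   # stem neck inclination, constant per implant
    epsilon_deg: float = 0.0   # stem varus relative to the femur
    chi_deg: float = 0.0       # stem anteversion
    side: Side = Side.RIGHT

    GAMMA_RANGE = (-10.0, 120.0)

    def __post_init__(self) -> None:
        if isinstance(self.side, str):
            self.side = Side[self.side]
        if not 90.0 <= self.delta_deg <= 160.0:
            raise ValueError(f"delta_deg out of range [90, 160]: {self.delta_deg}")
        if not -20.0 <= self.epsilon_deg <= 20.0:
            raise ValueError(f"epsilon_deg out of range [-20, 20]: {self.epsilon_deg}")
        if not -10.0 <= self.chi_deg <= 60.0:
            raise ValueError(f"chi_deg out of range [-10, 60]: {self.chi_deg}")

    def check_gamma(self, gamma_deg: float) -> float:
        g = _check_angle("gamma_deg", gamma_deg)
        lo, hi = self.GAMMA_RANGE
        if not lo <= g <= hi:
            raise ValueError(f"gamma_deg out of range [{lo}, {hi}]: {g}")
        return g

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "delta_deg": self.delta_deg,
            "epsilon_deg": self.epsilon_deg,
            "chi_deg": self.chi_deg,
            "side": self.side.value,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatientGeometry":
        d = json.loads(Path(path).read_text())
        return cls(delta_deg=d["delta_deg"], epsilon_deg=d["epsilon_deg"],
                   chi_deg=d["chi_deg"], side=Side[d.get("side", "RIGHT")])


def chain_matrix(geom: PatientGeometry, gamma_deg: float) -> np.ndarray:
    """Rotation carrying head-frame components into the pelvic frame.

    Ty(gamma) Tz(chi) Tx(epsilon) Tx(delta), delta applied innermost.
    """
    g = geom.check_gamma(gamma_deg)
    return rot_y(g) @ rot_z(geom.chi_deg) @ rot_x(geom.epsilon_deg) @ rot_x(geom.delta_deg)


def head_to_pelvis(f_prime: ForceVector, geom: PatientGeometry,
                   gamma_deg: float) -> ForceVector:
    """Transform a head-frame force into the pelvic frame at flexion gamma."""
    if f_prime.frame is not Frame.HEAD_OPRIME:
        raise ValueError(f"expected a HEAD_OPRIME force, got {f_prime.frame}")
    f = chain_matrix(geom, gamma_deg) @ f_prime.as_array()
    return ForceVector.from_array(f, Frame.PELVIS_O)


def pelvis_to_head(f: ForceVector, geom: PatientGeometry,
                   gamma_deg: float) -> ForceVector:
    """Inverse transform (used by the synthetic-data generator)."""
    if f.frame is not Frame.PELVIS_O:
        raise ValueError(f"expected a PELVIS_O force, got {f.frame}")
    fp = chain_matrix(geom, gamma_deg).T @ f.as_array()
    return ForceVector.from_array(fp, Frame.HEAD_OPRIME)


@dataclass(frozen=True)
class ReportedForce:
    """Force components in the clinical reporting convention.

    Positive values are forces directed posteriorly, inferiorly and
    medially; the resultant is the Euclidean magnitude.
    """

    posterior: float
    inferior: float
    medial: float
    resultant: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        r = math.sqrt(self.posterior ** 2 + self.inferior ** 2 + self.medial ** 2)
        if math.isnan(self.resultant):
            object.__setattr__(self, "resultant", r)
        elif not math.isclose(self.resultant, r, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("resultant inconsistent with components")


def to_reported(f: ForceVector, side: Side) -> ReportedForce:
    """Map a pelvic-frame force to the (posterior, inferior, medial) triple.

    Convention: posterior = -Fx (X is anterior); inferior = +Fz; medial =
    -Fy for a right hip and +Fy for a left hip.  With this assignment the
    mediolateral component is the one left invariant by the flexion
    rotation Ty(gamma), matching the observation that it changes little
    over the sweep while the supero-inferior and antero-posterior
    components trade off.
    """
    if f.frame is not Frame.PELVIS_O:
        raise ValueError(f"expected a PELVIS_O force, got {f.frame}")
    if not isinstance(side, Side):
        raise ValueError(f"unknown side: {side!r}")
    medial = -f.fy if side is Side.RIGHT else f.fy
    return ReportedForce(posterior=-f.fx, inferior=f.fz, medial=medial)


def reported_to_pelvis(posterior: float, inferior: float, medial: float,
                       side: Side) -> ForceVector:
    """Inverse of :func:`to_reported` (generator plumbing)."""
    fy = -medial if side is Side.RIGHT else medial
    return ForceVector(-posterior, fy, inferior, Frame.PELVIS_O)
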