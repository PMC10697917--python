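"""Forward model, calibration and inverse reconstruction for the sensor head.

The trial head carries four single-axis pressure sensors on the faces of a
14 mm cube inside a 26 mm hemisphere.  Each sensor registers only the
compressive component of the head-frame force along its outward normal,

    s_i = max(0, n_i . F') / gain_i + offset_i + noise,

so four one-sided channels resolve three signed force components: sensors
sit on +Z' (the taper axis, sensor #1), -Y' (the face toward the acetabulum
at neutral mounting), and an opposed +X'/-X' pair for the one axis whose
sign reverses between extension and flexion.

Calibration is ordinary least squares of raw signal against applied normal
load, channel by channel; reconstruction de-offsets and rescales the
channels to normal loads, folds opposed pairs into a signed load, and
solves the (generally overdetermined) linear system n_i . F' = l_i.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import Frame, ForceVector

__all__ = [
    "SensorLayout",
    "NoiseSpec",
    "ZERO_NOISE",
    "CalibrationModel",
    "CalibrationLoad",
    "ChannelSample",
    "project_force",
    "reconstruct_force",
    "calibrate",
    "run_calibration_benchmark",
    "BenchmarkResult",
]

SAMPLE_RATE_HZ = 100.0


def _default_normals() -> np.ndarray:
    return np.array([
        [0.0, 0.0, 1.0],    # 1: +Z', taper axis
        [1.0, 0.0, 0.0],    # 2: +X'
        [0.0, -1.0, 0.0],   # 3: -Y'
        [-1.0, 0.0, 0.0],   # 4: -X', opposed to #2
    ])


@dataclass
class SensorLayout:
    """Unit normals of the four sensing faces in the head frame O'."""

    normals: np.ndarray = field(default_factory=_default_normals)
    head_diameter_mm: float = 26.0
    cube_edge_mm: float = 14.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normals, dtype=float)
        if n.shape != (4, 3):
            raise ValueError("expected four 3-vectors")
        norms = np.linalg.norm(n, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor normals must be unit length")
        if np.linalg.matrix_rank(n) < 3:
            raise ValueError("sensor normals must span all three axes")
        self.normals = n


@dataclass
class NoiseSpec:
    """Channel noise model: multiplicative plus additive Gaussian.

    multiplicative_sigma is the fractional reading noise (1% default);
    additive_sigma_N is expressed as a Newton-equivalent at unit gain.
    """

    multiplicative_sigma: float = 0.01
    additive_sigma_N: float = 0.5

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(self.multiplicative_sigma * factor,
                         self.additive_sigma_N * factor)


ZERO_NOISE = NoiseSpec(0.0, 0.0)


@dataclass
class CalibrationModel:
    """Per-channel affine signal model: load = gain * (signal - offset)."""

    gains: np.ndarray = field(default_factory=lambda: np.ones(4))
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(4))
    layout: SensorLayout = field(default_factory=SensorLayout)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float).reshape(4)
        self.offsets = np.asarray(self.offsets, dtype=float).reshape(4)
        if not (self.gains > 0).all():
            raise ValueError("gains must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "gains": self.gains.tolist(),
            "offsets": self.offsets.tolist(),
            "normals": self.layout.normals.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(gains=np.array(d["gains"]), offsets=np.array(d["offsets"]),
                   layout=SensorLayout(normals=np.array(d["normals"])))


@dataclass(frozen=True)
class CalibrationLoad:
    """A benchtop load of known magnitude applied from direction (theta, phi).

    theta is the polar angle from +Z' and phi the azimuth from +X' rotated
    toward -Y', so the benchtop protocol envelope (theta in [30, 90], phi in
    [0, 45], 15 degree steps) presses on the instrumented faces.
    """

    magnitude_N: float
    theta_deg: float
    phi_deg: float

    def __post_init__(self) -> None:
        if not self.magnitude_N > 0:
            raise ValueError("load magnitude must be positive")

    def force(self) -> ForceVector:
        th = math.radians(self.theta_deg)
        ph = math.radians(self.phi_deg)
        return ForceVector(
            self.magnitude_N * math.sin(th) * math.cos(ph),
            -self.magnitude_N * math.sin(th) * math.sin(ph),
            self.magnitude_N * math.cos(th),
            Frame.HEAD_OPRIME,
        )


@dataclass(frozen=True)
class ChannelSample:
    """One 100 Hz logger sample: time and the four raw channel counts."""

    t: float
    s1: float
    s2: float
    s3: float
    s4: float

    def signals(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4])


def _apply_noise(signals: np.ndarray, gains: np.ndarray, noise: NoiseSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = signals * (1.0 + noise.multiplicative_sigma * rng.standard_normal(signals.shape))
    # additive noise is specified in Newton equivalents; divide by gain to
    # express it in raw counts on each channel
    out = out + (noise.additive_sigma_N / gains) * rng.standard_normal(signals.shape)
    return out


def project_force(f_prime: ForceVector, cal: CalibrationModel,
                  noise: NoiseSpec = ZERO_NOISE,
                  rng: np.random.Generator | int | None = None,
                  t: float = 0.0) -> ChannelSample:
    """Forward model: head-frame force to the four raw channel signals."""
    if f_prime.frame is not Frame.HEAD_OPRIME:
        raise ValueError(f"expected a HEAD_OPRIME force, got {f_prime.frame}")
    loads = np.maximum(0.0, cal.layout.normals @ f_prime.as_array())
    signals = loads / cal.gains + cal.offsets
    if noise.multiplicative_sigma or noise.additive_sigma_N:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        clean_counts = loads / cal.gains
        signals = cal.offsets + _apply_noise(clean_counts, cal.gains, noise, rng)
    return ChannelSample(t, *signals)


def project_series(forces: np.ndarray, cal: CalibrationModel,
                   noise: NoiseSpec = ZERO_NOISE,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Vectorised forward model: (n, 3) head-frame forces to (n, 4) signals."""
    loads = np.maximum(0.0, forces @ cal.layout.normals.T)
    counts = loads / cal.gains
    if noise.multiplicative_sigma or noise.additive_sigma_N:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        counts = counts * (1.0 + noise.multiplicative_sigma * rng.standard_normal(counts.shape))
        counts = counts + (noise.additive_sigma_N / cal.gains) * rng.standard_normal(counts.shape)
    return counts + cal.offsets


def _paired_system(layout: SensorLayout) -> tuple[np.ndarray, list[tuple[int, int]], list[int]]:
    """Group opposed sensor pairs; return design rows and index bookkeeping."""
    n = layout.normals
    paired: list[tuple[int, int]] = []
    used: set[int] = set()
    for i in range(4):
        if i in used:
            continue
        for j in range(i + 1, 4):
            if j not in used and np.allclose(n[i], -n[j], atol=1e-9):
                paired.append((i, j))
                used.update((i, j))
                break
    single = [i for i in range(4) if i not in used]
    rows = [n[i] for i, _ in paired] + [n[i] for i in single]
    return np.array(rows), paired, single


def reconstruct_force(sample: ChannelSample, cal: CalibrationModel
                      ) -> tuple[ForceVector, bool]:
    """Invert the sensor model; returns (force, no_load_flag).

    Opposed pairs are folded into a signed load (their rectifications are
    mutually exclusive); single one-sided sensors contribute their
    rectified load directly.  The resulting linear system is solved by
    least squares.
    """
    signals = sample.signals()
    loads = cal.gains * (signals - cal.offsets)
    if not np.isfinite(loads).all():
        raise ValueError("non-finite channel signals")
    no_load = bool((loads <= 0).all())
    loads = np.maximum(loads, 0.0)
    rows, paired, single = _paired_system(cal.layout)
    rhs = [loads[i] - loads[j] for i, j in paired] + [loads[i] for i in single]
    f, *_ = np.linalg.lstsq(rows, np.array(rhs), rcond=None)
    if no_load:
        f = np.zeros(3)
    return ForceVector.from_array(f, Frame.HEAD_OPRIME), no_load


def reconstruct_series(signals: np.ndarray, cal: CalibrationModel
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised inverse: (n, 4) signals to ((n, 3) forces, no-load mask)."""
    loads = cal.gains * (np.asarray(signals, dtype=float) - cal.offsets)
    no_load = (loads <= 0).all(axis=1)
    loads = np.maximum(loads, 0.0)
    rows, paired, single = _paired_system(cal.layout)
    rhs = np.column_stack([loads[:, i] - loads[:, j] for i, j in paired]
                          + [loads[:, i] for i in single])
    pinv = np.linalg.pinv(rows)
    forces = rhs @ pinv.T
    forces[no_load] = 0.0
    return forces, no_load


def calibrate(loads: list[CalibrationLoad], samples: list[ChannelSample],
              layout: SensorLayout | None = None) -> CalibrationModel:
    """Fit per-channel (gain, offset) by OLS of signal vs applied normal load.

    Channels never excited by the supplied loads keep unit gain / zero
    offset and are flagged in the diagnostics.
    """
    if len(loads) != len(samples):
        raise ValueError("loads and samples must pair up")
    layout = layout or SensorLayout()
    applied = np.array([ld.force().as_array() for ld in loads])
    normal_loads = np.maximum(0.0, applied @ layout.normals.T)  # (n, 4)
    signals = np.array([s.signals() for s in samples])
    gains, offsets = np.ones(4), np.zeros(4)
    diag: dict = {"residual_rms": [None] * 4, "unexcited": []}
    for ch in range(4):
        x = normal_loads[:, ch]
        if np.ptp(x) < 1e-12:
            if x.max() < 1e-12:
                diag["unexcited"].append(ch)
                continue
            raise ValueError(
                f"rank-deficient calibration design on channel {ch + 1}: "
                "all applied normal loads identical")
        design = np.column_stack([x, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(design, signals[:, ch], rcond=None)
        slope, intercept = coef
        if slope <= 0:
            raise ValueError(f"non-positive fitted slope on channel {ch + 1}")
        gains[ch] = 1.0 / slope
        offsets[ch] = intercept
        pred = design @ coef
        diag["residual_rms"][ch] = float(np.sqrt(np.mean((signals[:, ch] - pred) ** 2)))
    return CalibrationModel(gains=gains, offsets=offsets, layout=layout,
                            diagnostics=diag)


PROTOCOL_THETA_DEG = (30.0, 45.0, 60.0, 75.0, 90.0)
PROTOCOL_PHI_DEG = (0.0, 15.0, 30.0, 45.0)
PROTOCOL_REPEATS = 3
BENCH_MAGNITUDES_N = tuple(float(m) for m in range(50, 801, 150))


def protocol_grid(magnitudes: tuple[float, ...] = BENCH_MAGNITUDES_N,
                  repeats: int = PROTOCOL_REPEATS) -> list[CalibrationLoad]:
    """The benchtop loading protocol: the (theta, phi) grid, repeated."""
    return [CalibrationLoad(m, th, ph)
            for _ in range(repeats)
            for th in PROTOCOL_THETA_DEG
            for ph in PROTOCOL_PHI_DEG
            for m in magnitudes]


@dataclass(frozen=True)
class BenchmarkResult:
    mean_abs_magnitude_error_pct: float
    mean_abs_angle_error_deg: float
    n_loads: int


def run_calibration_benchmark(cal: CalibrationModel | None = None,
                              noise: NoiseSpec | None = None,
                              seed: int | np.random.Generator = 0
                              ) -> BenchmarkResult:
    """Simulate the benchtop accuracy study on the full protocol grid.

    Every protocol load is pushed through the noisy forward model and
    reconstructed; returns the mean absolute force-magnitude error (% of
    the true magnitude) and the mean absolute angle between true and
    reconstructed force vectors (degrees).
    """
    cal = cal or CalibrationModel()
    noise = noise if noise is not None else NoiseSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = protocol_grid()
    true = np.array([ld.force().as_array() for ld in grid])
    signals = project_series(true, cal, noise, rng)
    recon, _ = reconstruct_series(signals, cal)
    mag_t = np.linalg.norm(true, axis=1)
    mag_r = np.linalg.norm(recon, axis=1)
    mag_err_pct = 100.0 * np.abs(mag_r - mag_t) / mag_t
    cosang = np.einsum("ij,ij->i", true, recon) / np.maximum(mag_t * mag_r, 1e-300)
    ang_err = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return BenchmarkResult(float(mag_err_pct.mean()), float(np.abs(ang_err).mean()),
                           len(grid))
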