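"""Synthetic ground-truth trajectories, sensor logs and virtual cohorts.

The generator emulates what the instrumented head sees during passive
flexion trials: the resultant soft-tissue force follows a U-shaped
profile over the sweep - largest with the hip extended, dipping to a
minimum in mid-flexion, rising again toward 90 degrees - while its
direction rotates from supero(-anterior) toward posterior as the hip
flexes, with a roughly constant mediolateral component.

A :class:`VirtualPatientSpec` pins the profile with four anchors
(force at 0 degrees, minimum force and its angle, force at 90 degrees),
interpolated with a shape-preserving monotone cubic so the resultant
never undershoots the specified minimum.  The component split is
controlled by two crossover angles: the flexion angle at which the
antero-posterior component changes sign and the angle at which the
supero-inferior component does.

Recordings are produced by running the truth backwards through the
measurement chain: pelvic force -> head frame (inverse Euler chain) ->
sensor faces (compression-only projection, optional noise) -> 100 Hz log.
Cohorts draw per-patient anchor magnitudes from log-normal distributions,
reflecting the large, right-skewed spread of soft-tissue tension between
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .frames import PatientGeometry, chain_matrix, reported_to_pelvis
from .sensors import SAMPLE_RATE_HZ, CalibrationModel, NoiseSpec, ZERO_NOISE, \
    project_series
from .trials import CycleSummary, TrialRecording

__all__ = [
    "VirtualPatientSpec",
    "CohortSpec",
    "truth_trajectory",
    "generate_recording",
    "generate_cohort",
    "patient4_spec",
]

HALF_SWEEP_S = 15.0  # slow passive motion: 15 s per 0->90 ramp


@dataclass
class VirtualPatientSpec:
    """Ground-truth force profile and measurement setup for one patient."""

    f_ext_N: float = 186.9        # resultant at 0 deg (most extended)
    f_min_N: float = 93.0         # minimum resultant over the sweep
    gamma_min_deg: float = 15.7   # flexion angle of that minimum
    f_90_N: float = 155.1         # resultant at 90 deg flexion
    gamma_ap_deg: float = 10.0    # antero-posterior component zero crossing
    gamma_si_deg: float = 90.0    # supero-inferior component zero crossing
    medial_frac: float = 0.45     # constant medial force as fraction of f_min
    geometry: PatientGeometry = field(default_factory=PatientGeometry)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_cycles: int = 3
    seed: int = 0
    patient_id: str = "virtual"

    def __post_init__(self) -> None:
        if not self.f_min_N <= min(self.f_ext_N, self.f_90_N):
            raise ValueError("f_min must not exceed the endpoint forces")
        if not 0.0 < self.gamma_min_deg < 90.0:
            raise ValueError("gamma_min must lie strictly inside (0, 90)")
        if not 0.0 < self.medial_frac < 1.0:
            raise ValueError("medial_frac must lie in (0, 1)")
        if self.gamma_si_deg <= self.gamma_ap_deg:
            raise ValueError("gamma_si must exceed gamma_ap")

    def resultant(self, gamma_deg) -> np.ndarray:
        interp = PchipInterpolator(
            [0.0, self.gamma_min_deg, 90.0],
            [self.f_ext_N, self.f_min_N, self.f_90_N])
        return np.asarray(interp(np.asarray(gamma_deg, dtype=float)))

    def truth_summary(self) -> CycleSummary:
        return CycleSummary(self.f_ext_N, self.f_min_N, self.gamma_min_deg,
                            self.f_90_N)


def truth_trajectory(spec: VirtualPatientSpec, gamma_grid) -> pd.DataFrame:
    """Ground-truth pelvic force along a flexion grid.

    Columns: gamma_deg, posterior_N, inferior_N, medial_N, resultant_N and
    the pelvic-frame components fx/fy/fz.  The three reported components
    recombine exactly to the specified resultant.
    """
    g = np.asarray(gamma_grid, dtype=float)
    F = spec.resultant(g)
    m0 = spec.medial_frac * spec.f_min_N
    if (F < m0).any():
        raise ValueError("medial component exceeds the resultant")
    r = np.sqrt(F ** 2 - m0 ** 2)
    psi = np.radians(90.0 * (g - spec.gamma_ap_deg)
                     / (spec.gamma_si_deg - spec.gamma_ap_deg))
    posterior = r * np.sin(psi)
    inferior = -r * np.cos(psi)
    medial = np.full_like(g, m0)
    side = spec.geometry.side
    pelvic = np.array([
        reported_to_pelvis(p, i, m, side).as_array()
        for p, i, m in zip(posterior, inferior, medial)
    ])
    return pd.DataFrame({
        "gamma_deg": g, "posterior_N": posterior, "inferior_N": inferior,
        "medial_N": medial, "resultant_N": F,
        "fx": pelvic[:, 0], "fy": pelvic[:, 1], "fz": pelvic[:, 2],
    })


def _triangle_gamma(n_cycles: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangular 0->90->0 flexion trace at 100 Hz, ``n_cycles`` repeats."""
    half = int(round(HALF_SWEEP_S * SAMPLE_RATE_HZ))
    up = np.linspace(0.0, 90.0, half + 1)
    down = up[::-1][1:]
    cycle = np.concatenate([up, down])
    g = np.concatenate([cycle[:-1]] * n_cycles + [np.array([0.0])])
    t = np.arange(len(g)) / SAMPLE_RATE_HZ
    return t, g


def generate_recording(spec: VirtualPatientSpec,
                       cal: CalibrationModel | None = None
                       ) -> tuple[TrialRecording, CycleSummary]:
    """Synthesise a full trial log plus its ground-truth cycle summary.

    Deterministic given ``spec.seed``; zero noise reproduces the truth to
    within interpolation error when run back through the pipeline.
    """
    cal = cal or CalibrationModel()
    rng = np.random.default_rng(spec.seed)
    t, g = _triangle_gamma(spec.n_cycles)
    truth = truth_trajectory(spec, g)
    pelvic = truth[["fx", "fy", "fz"]].to_numpy()
    head = np.array([chain_matrix(spec.geometry, gi).T @ f
                     for gi, f in zip(g, pelvic)])
    signals = project_series(head, cal, spec.noise, rng)
    rec = TrialRecording(t, signals, g, spec.geometry, spec.patient_id)
    return rec, spec.truth_summary()


def patient4_spec(noise: NoiseSpec = ZERO_NOISE, seed: int = 0,
                  **overrides) -> VirtualPatientSpec:
    """Spec anchored to the smallest patient of the measured series
    (186.9 / 93.0 N anchors, minimum at 15.7 deg, 155.1 N at 90 deg)."""
    return VirtualPatientSpec(noise=noise, seed=seed,
                              patient_id="patient4", **overrides)


# Cohort-level defaults: the measured four-patient series' cohort means and
# intersubject spreads for the four trial metrics.
_COHORT_DEFAULTS = {
    "f_ext_N": (418.7, 0.583),
    "f_min_N": (120.0, 0.165),
    "gamma_min_deg": (32.8, 0.402),
    "f_90_N": (204.5, 0.242),
}


@dataclass
class CohortSpec:
    """Distributional description of a virtual patient cohort.

    ``metrics`` maps each anchor to (mean, coefficient of variation); the
    anchors are drawn log-normally with that mean and CV.
    """

    n_patients: int = 4
    metrics: dict = field(default_factory=lambda: dict(_COHORT_DEFAULTS))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_cycles: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least two patients")
        for name, (mean, cv) in self.metrics.items():
            if mean <= 0 or cv < 0:
                raise ValueError(f"invalid (mean, cv) for {name}")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int
               ) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def draw_patient_specs(spec: CohortSpec) -> list[VirtualPatientSpec]:
    """Draw per-patient anchor values from the cohort distributions."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    draws = {k: _lognormal(rng, m, cv, n) for k, (m, cv) in spec.metrics.items()}
    out = []
    for k in range(n):
        f_ext = float(draws["f_ext_N"][k])
        f_90 = float(draws["f_90_N"][k])
        f_min = float(min(draws["f_min_N"][k], 0.95 * min(f_ext, f_90)))
        g_min = float(np.clip(draws["gamma_min_deg"][k], 5.0, 85.0))
        out.append(VirtualPatientSpec(
            f_ext_N=f_ext, f_min_N=f_min, gamma_min_deg=g_min, f_90_N=f_90,
            noise=spec.noise, n_cycles=spec.n_cycles,
            seed=int(rng.integers(2 ** 31 - 1)),
            patient_id=f"virtual-{k + 1:02d}"))
    return out


def generate_cohort(spec: CohortSpec,
                    cal: CalibrationModel | None = None,
                    patient_specs: list[VirtualPatientSpec] | None = None
                    ) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Generate recordings for a cohort plus a truth table of the anchors.

    Pass ``patient_specs`` to bypass the distributional draw and simulate
    a fixed set of patients instead.
    """
    specs = patient_specs if patient_specs is not None else draw_patient_specs(spec)
    recordings, rows = [], []
    for ps in specs:
        rec, truth = generate_recording(ps, cal)
        recordings.append(rec)
        rows.append({"patient_id": ps.patient_id, **truth.as_dict()})
    return recordings, pd.DataFrame(rows)
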