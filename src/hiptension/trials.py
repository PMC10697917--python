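"""Trial processing: from a sensor log to per-cycle and cohort statistics.

A trial takes the anaesthetised hip through passive flexion from 0 to 90
degrees three times while the instrumented head logs four channels at
100 Hz together with the flexion angle.  This module reconstructs the
head-frame force per sample, carries it into the pelvic frame, segments
the flexion trace into rising sweeps, and extracts per cycle:

* maximum force  - the resultant at the most-extended posture,
* minimum force  - the global minimum of the resultant over the cycle,
* the flexion angle at that minimum,
* the force at 90 degrees of flexion (linear interpolation in gamma).

Repeatability within a patient and spread across patients are summarised
with the coefficient of variation, COV% = 100 * sd / mean (sample sd,
n - 1 denominator).  Cohort numbers are means of patient means; the
intersubject COV is the COV across patient means and the mean
intrasubject COV averages the per-patient COVs, skipping patients whose
COV is undefined (fewer than two valid cycles).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import Frame, PatientGeometry, chain_matrix
from .sensors import SAMPLE_RATE_HZ, CalibrationModel, reconstruct_series

__all__ = [
    "TrialRecording",
    "CycleSummary",
    "PatientSummary",
    "CohortStats",
    "segment_cycles",
    "summarize_cycle",
    "cov_pct",
    "cohort_stats",
    "run_trial",
    "METRICS",
]

METRICS = ("max_force_N", "min_force_N", "gamma_at_min_deg", "force_at_90_N")

SMOOTH_WINDOW_S = 0.25
MIN_CYCLE_SAMPLES = 10


@dataclass
class TrialRecording:
    """A 100 Hz multichannel sensor log with its flexion-angle trace."""

    t: np.ndarray                 # seconds
    signals: np.ndarray           # (n, 4) raw channel counts
    gamma_deg: np.ndarray         # flexion angle per sample
    geometry: PatientGeometry
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.gamma_deg = np.asarray(self.gamma_deg, dtype=float)
        n = len(self.t)
        if self.signals.shape != (n, 4) or len(self.gamma_deg) != n:
            raise ValueError("t, signals and gamma_deg lengths disagree")
        lo, hi = PatientGeometry.GAMMA_RANGE
        finite = self.gamma_deg[np.isfinite(self.gamma_deg)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError("flexion angle outside the plausible range")
        if n > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / SAMPLE_RATE_HZ, rtol=0.01):
                raise ValueError("sampling interval inconsistent with 100 Hz")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "t": self.t,
            "s1": self.signals[:, 0], "s2": self.signals[:, 1],
            "s3": self.signals[:, 2], "s4": self.signals[:, 3],
            "gamma_deg": self.gamma_deg,
        })
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path, geometry: PatientGeometry,
                 patient_id: str = "anon") -> "TrialRecording":
        df = pd.read_csv(path)
        required = {"t", "s1", "s2", "s3", "s4", "gamma_deg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sensor log {path} missing columns: {sorted(missing)}")
        return cls(df["t"].to_numpy(), df[["s1", "s2", "s3", "s4"]].to_numpy(),
                   df["gamma_deg"].to_numpy(), geometry, patient_id)


def _smooth(x: np.ndarray, window_s: float = SMOOTH_WINDOW_S) -> np.ndarray:
    """Centred moving average; preserves length, NaNs propagate."""
    w = max(1, int(round(window_s * SAMPLE_RATE_HZ)))
    if w % 2 == 0:
        w += 1
    if w == 1 or len(x) < w:
        return np.asarray(x, dtype=float)
    kernel = np.ones(w) / w
    pad = w // 2
    # odd reflection keeps the moving average exact for locally linear
    # signals at the boundaries (no flattening of the 0-degree peak)
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    xp = np.concatenate([left, x, right])
    return np.convolve(xp, kernel, mode="valid")


def segment_cycles(gamma_deg: np.ndarray, low_deg: float = 5.0,
                   high_deg: float = 85.0) -> list[tuple[int, int]]:
    """Find rising flexion sweeps from below ``low_deg`` to above ``high_deg``.

    Returns half-open index ranges, one per complete sweep.  The angle
    trace is smoothed first so sensor noise does not split a sweep.
    """
    g = np.asarray(gamma_deg, dtype=float)
    if len(g) < 2:
        return []
    gs = _smooth(np.nan_to_num(g, nan=np.nanmedian(g) if np.isfinite(g).any() else 0.0))
    ranges: list[tuple[int, int]] = []
    n = len(gs)
    i = 0
    while i < n - 1:
        # advance to the start of the next rising stretch
        while i < n - 1 and gs[i + 1] <= gs[i] + 1e-12:
            i += 1
        if i >= n - 1:
            break
        j = i  # expand while non-decreasing (inclusive end)
        while j < n - 1 and gs[j + 1] >= gs[j] - 1e-9:
            j += 1
        if gs[i] < low_deg and gs[j] > high_deg:
            ranges.append((i, j + 1))
        i = max(j, i + 1)
    return ranges


@dataclass(frozen=True)
class CycleSummary:
    max_force_N: float
    min_force_N: float
    gamma_at_min_deg: float
    force_at_90_N: float

    def __post_init__(self) -> None:
        if self.min_force_N > self.force_at_90_N + 1e-9 or \
           self.min_force_N > self.max_force_N + 1e-9:
            raise ValueError("minimum force exceeds another cycle metric")

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


def summarize_cycle(resultant_N: np.ndarray, gamma_deg: np.ndarray,
                    smooth: bool = True) -> CycleSummary:
    """Extract the four trial metrics from one rising flexion sweep.

    The maximum force is anchored to the most-extended sample (minimum
    gamma), not the global maximum; the two coincide for the U-shaped
    profiles seen in practice.  Ties at the force minimum resolve to the
    earliest sample.  The force at 90 degrees is linearly interpolated in
    gamma, falling back to the last sample when the sweep stops between
    85 and 90 degrees.
    """
    r = np.asarray(resultant_N, dtype=float)
    g = np.asarray(gamma_deg, dtype=float)
    if len(r) != len(g):
        raise ValueError("resultant and gamma lengths disagree")
    if len(r) < MIN_CYCLE_SAMPLES:
        raise ValueError(f"cycle shorter than {MIN_CYCLE_SAMPLES} samples")
    if not (np.isfinite(r).all() and np.isfinite(g).all()):
        raise ValueError("non-finite samples in cycle")
    if smooth:
        r = _smooth(r)
        g = _smooth(g)
    i_ext = int(np.argmin(g))
    i_min = int(np.argmin(r))  # argmin takes the earliest tie
    min_force, gamma_at_min = _refine_minimum(
        np.asarray(gamma_deg, dtype=float), np.asarray(resultant_N, dtype=float),
        float(g[i_min]), float(r[i_min]))
    gmax = g.max()
    if gmax >= 90.0:
        order = np.argsort(g, kind="stable")
        f90 = float(np.interp(90.0, g[order], r[order]))
    elif gmax >= 85.0:
        f90 = float(r[int(np.argmax(g))])
    else:
        raise ValueError("cycle does not reach 85 degrees of flexion")
    return CycleSummary(
        max_force_N=float(r[i_ext]),
        min_force_N=float(min(min_force, r[i_ext], f90)),
        gamma_at_min_deg=float(np.clip(gamma_at_min, 0.0, 90.0)),
        force_at_90_N=f90,
    )


def _refine_minimum(g_raw: np.ndarray, r_raw: np.ndarray,
                    g0: float, r0: float) -> tuple[float, float]:
    """Robust (min force, gamma-at-min) via a shape-constrained profile fit.

    The force valley in mid-flexion is shallow, so the pointwise argmin
    wanders by several degrees under Newton-level noise.  When the cycle
    is clearly U-shaped, a three-anchor monotone-cubic resultant profile
    (force at the extension end, minimum force and its angle, force at
    the flexion end) is fitted to the raw samples by least squares, and
    its minimum anchor is reported.  For flat or monotone profiles the
    discrete minimum (earliest sample on ties) is kept.
    """
    from scipy.interpolate import PchipInterpolator
    from scipy.optimize import least_squares

    finite = np.isfinite(g_raw) & np.isfinite(r_raw)
    g, r = g_raw[finite], r_raw[finite]
    if len(g) < 20:
        return r0, g0
    g_lo, g_hi = float(g.min()), float(g.max())
    if g_hi - g_lo < 10.0:
        return r0, g0
    # noise scale from first differences (smooth trend cancels)
    sigma = float(np.median(np.abs(np.diff(r)))) / (1.4826 * math.sqrt(2)) \
        if len(r) > 3 else 0.0
    depth = max(3.0 * sigma, 0.01 * max(r0, 1e-12))
    r_ends = (float(r[np.argmin(g)]), float(r[np.argmax(g)]))
    if not (r_ends[0] - r0 > depth and r_ends[1] - r0 > depth):
        return r0, g0  # not U-shaped: keep the discrete minimum
    span = g_hi - g_lo

    def model(p):
        fe, fm, gm, f9 = p
        fm = min(fm, fe, f9)
        return PchipInterpolator([g_lo, gm, g_hi], [fe, fm, f9])(g)

    p0 = [r_ends[0], r0, float(np.clip(g0, g_lo + 0.02 * span, g_hi - 0.02 * span)),
          r_ends[1]]
    try:
        sol = least_squares(
            lambda p: model(p) - r, p0,
            bounds=([0, 0, g_lo + 0.01 * span, 0],
                    [np.inf, np.inf, g_hi - 0.01 * span, np.inf]))
    except Exception:
        return r0, g0
    fe, fm, gm, f9 = sol.x
    fm = float(min(fm, fe, f9))
    return fm, float(gm)


def cov_pct(values) -> float:
    """Coefficient of variation in percent: 100 * sample sd / mean.

    Returns NaN for fewer than two finite values or a zero mean (flagged
    rather than raised so patients with limited data propagate as missing,
    mirroring how incomplete trials are reported).
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return float("nan")
    m = v.mean()
    if math.isclose(m, 0.0, abs_tol=1e-300):
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


@dataclass
class PatientSummary:
    """Per-cycle metrics plus mean / range / COV% aggregates for one patient."""

    patient_id: str
    cycles: list[CycleSummary]
    flags: list[str] = field(default_factory=list)

    def metric_values(self, metric: str) -> np.ndarray:
        return np.array([getattr(c, metric) for c in self.cycles], dtype=float)

    def mean(self, metric: str) -> float:
        v = self.metric_values(metric)
        return float(v.mean()) if len(v) else float("nan")

    def value_range(self, metric: str) -> tuple[float, float]:
        v = self.metric_values(metric)
        if not len(v):
            return (float("nan"), float("nan"))
        return (float(v.min()), float(v.max()))

    def cov(self, metric: str) -> float:
        return cov_pct(self.metric_values(metric))

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_cycles": len(self.cycles),
            "flags": self.flags,
            "cycles": [c.as_dict() for c in self.cycles],
            "metrics": {
                m: {"mean": self.mean(m), "range": list(self.value_range(m)),
                    "cov_pct": self.cov(m)}
                for m in METRICS
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatientSummary":
        d = json.loads(Path(path).read_text())
        cycles = [CycleSummary(**c) for c in d["cycles"]]
        return cls(d["patient_id"], cycles, d.get("flags", []))


@dataclass
class CohortStats:
    """Cohort aggregates per metric, mirroring a multi-patient summary table."""

    n_patients: int
    mean: dict[str, float]
    mean_intrasubject_cov_pct: dict[str, float]
    intersubject_cov_pct: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": list(METRICS),
            "cohort_mean": [self.mean[m] for m in METRICS],
            "mean_intrasubject_cov_pct": [self.mean_intrasubject_cov_pct[m] for m in METRICS],
            "intersubject_cov_pct": [self.intersubject_cov_pct[m] for m in METRICS],
        })


def cohort_stats(patients: list[PatientSummary]) -> CohortStats:
    """Aggregate patient summaries: mean of patient means, COV across and
    within patients.  Patients with an undefined COV on a metric are
    excluded from that metric's mean intrasubject COV."""
    if len(patients) < 2:
        raise ValueError("cohort statistics need at least two patients")
    mean, intra, inter = {}, {}, {}
    for m in METRICS:
        pmeans = np.array([p.mean(m) for p in patients])
        mean[m] = float(np.nanmean(pmeans))
        inter[m] = cov_pct(pmeans)
        pcovs = np.array([p.cov(m) for p in patients])
        pcovs = pcovs[np.isfinite(pcovs)]
        intra[m] = float(pcovs.mean()) if len(pcovs) else float("nan")
    return CohortStats(len(patients), mean, intra, inter)


def run_trial(recording: TrialRecording, cal: CalibrationModel) -> PatientSummary:
    """Full per-patient pipeline: reconstruct, transform, segment, summarise.

    Cycles that fail their summary (too short, corrupted samples, no load)
    are flagged by index and excluded from the aggregates rather than
    silently dropped.
    """
    forces_head, no_load = reconstruct_series(recording.signals, cal)
    n = len(forces_head)
    resultant = np.full(n, np.nan)
    ok = np.isfinite(forces_head).all(axis=1) & np.isfinite(recording.gamma_deg)
    # rotations preserve the norm, so the reported resultant equals the
    # head-frame magnitude; pelvic components are computed on demand
    resultant[ok] = np.linalg.norm(forces_head[ok], axis=1)
    resultant[no_load] = np.nan

    ranges = segment_cycles(recording.gamma_deg)
    cycles: list[CycleSummary] = []
    flags: list[str] = []
    if not ranges:
        flags.append("segmentation: no complete 0-90 flexion sweep found")
    for k, (a, b) in enumerate(ranges):
        try:
            cycles.append(summarize_cycle(resultant[a:b], recording.gamma_deg[a:b]))
        except ValueError as exc:
            flags.append(f"cycle {k}: {exc}")
    if cycles and len(cycles) < 2:
        flags.append("cov: undefined with fewer than two valid cycles")
    return PatientSummary(recording.patient_id, cycles, flags)


def pelvic_components(recording: TrialRecording, cal: CalibrationModel
                      ) -> pd.DataFrame:
    """Per-sample reported force components (posterior, inferior, medial)."""
    from .frames import ForceVector, to_reported

    forces_head, no_load = reconstruct_series(recording.signals, cal)
    rows = []
    for k in range(len(forces_head)):
        g = recording.gamma_deg[k]
        if no_load[k] or not (np.isfinite(forces_head[k]).all() and np.isfinite(g)):
            rows.append((recording.t[k], g, np.nan, np.nan, np.nan, np.nan))
            continue
        lo, hi = PatientGeometry.GAMMA_RANGE
        g = float(np.clip(g, lo, hi))
        fp = chain_matrix(recording.geometry, g) @ forces_head[k]
        rep = to_reported(ForceVector.from_array(fp, Frame.PELVIS_O),
                          recording.geometry.side)
        rows.append((recording.t[k], g, rep.posterior, rep.inferior,
                     rep.medial, rep.resultant))
    return pd.DataFrame(rows, columns=["t", "gamma_deg", "posterior_N",
                                       "inferior_N", "medial_N", "resultant_N"])
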