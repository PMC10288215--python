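"""Interlimb coordination: phase/gap intervals, symmetry indexes, and
circular statistics.

Temporal coupling between two limbs is the phase interval: the absolute
time between their contacts divided by the reference limb's cycle duration,
times 360 (degrees; 0/360 = in-phase, 180 = strict alternation).  Spatial
coupling between homologous limbs is the gap interval: step length divided
by the reference limb's stride length, times 360 (180 = the trailing paw
lands half a stride behind).  Symmetry indexes express the deviation of
either interval from the perfectly symmetric 180 deg as a percentage.

Circular samples are summarized by the mean direction and resultant vector
length r (1 = fully concentrated, 0 = uniform/balanced); deviation from
uniformity is assessed with Rayleigh's test and differences in mean
direction between conditions with the Watson-Williams test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import COUPLINGS, GAP_COUPLINGS
from .kinematics import GaitEventSeries, step_length, stride_length


# ---------------------------------------------------------------------------
# interval measures

def phase_interval(ref_onset: float, ref_duration: float, other_contact: float) -> float:
    """Phase of the other limb's contact within the reference cycle, deg."""
    if ref_duration <= 0:
        raise ValueError("reference cycle duration must be positive")
    if not (ref_onset <= other_contact < ref_onset + ref_duration):
        raise ValueError("other limb's contact lies outside the reference cycle")
    return float(((other_contact - ref_onset) / ref_duration * 360.0) % 360.0)


def gap_interval(step_len: float, ref_stride_len: float) -> float:
    """Spatial coupling: step length over the reference stride length, deg."""
    if not ref_stride_len > 0:
        raise ValueError("reference stride length must be positive")
    return float((step_len / ref_stride_len * 360.0) % 360.0)


def symmetry_index(angle_deg: float) -> float:
    """Percent deviation of a phase/gap interval from 180 deg (0 = perfect
    left-right symmetry, 100 = complete asymmetry)."""
    a = np.asarray(angle_deg, dtype=float)
    if np.any((a < 0) | (a > 360)):
        raise ValueError("angle must lie in [0, 360]")
    out = np.abs(a - 180.0) / 180.0 * 100.0
    return float(out) if np.isscalar(angle_deg) else out


def phase_intervals(ref: GaitEventSeries, other: GaitEventSeries) -> np.ndarray:
    """Per-cycle phase intervals (deg) of ``other`` relative to ``ref``;
    NaN for reference cycles without a contact of the other limb."""
    c_ref = ref.contact_times
    out = np.full(len(c_ref) - 1, np.nan)
    for i in range(len(c_ref) - 1):
        onset, dur = c_ref[i], c_ref[i + 1] - c_ref[i]
        inside = other.contact_times[
            (other.contact_times >= onset) & (other.contact_times < onset + dur)
        ]
        if inside.size:
            out[i] = phase_interval(onset, dur, float(inside[0]))
    return out


def gap_intervals(ref: GaitEventSeries, other: GaitEventSeries) -> np.ndarray:
    """Per-cycle gap intervals (deg) for a homologous pair, NaN where the
    trailing limb's position or the stride is unavailable."""
    out = np.full(ref.n_cycles, np.nan)
    for i in range(ref.n_cycles):
        step = step_length(ref, other, i)
        stride = stride_length(ref, i)
        if np.isfinite(step) and np.isfinite(stride) and stride > 0:
            out[i] = gap_interval(step, stride)
    return out


def coupling_angles(
    all_series: dict[str, GaitEventSeries], pair: str, kind: str = "phase"
) -> np.ndarray:
    """Interval series (deg) for one named limb coupling.

    The reference limb is the left forelimb, except for the homologous
    hindlimb coupling where it is the left hindlimb.  Gap intervals exist
    only for the homologous (forelimb, hindlimb) couplings.
    """
    if pair not in COUPLINGS:
        raise ValueError(f"unknown coupling {pair!r}")
    ref_limb, other_limb = COUPLINGS[pair]
    if kind == "phase":
        angles = phase_intervals(all_series[ref_limb], all_series[other_limb])
    elif kind == "gap":
        if pair not in GAP_COUPLINGS:
            raise ValueError("gap intervals are defined only for homologous couplings")
        angles = gap_intervals(all_series[ref_limb], all_series[other_limb])
    else:
        raise ValueError("kind must be 'phase' or 'gap'")
    return angles[np.isfinite(angles)]


# ---------------------------------------------------------------------------
# circular statistics

@dataclass
class CircularSample:
    """A set of angles (deg) with its circular mean direction and resultant
    vector length r.  ``mean_direction`` is NaN when r vanishes (the mean
    unit-vector sum has no direction)."""

    angles: np.ndarray
    mean_direction: float
    r: float

    @property
    def n(self) -> int:
        return len(self.angles)


def circ_mean_r(angles_deg) -> CircularSample:
    """Mean direction (deg, in [0, 360)) and resultant length of a sample."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one angle")
    rad = np.deg2rad(a)
    z = np.mean(np.exp(1j * rad))
    r = float(np.abs(z))
    if r < 1e-12:
        warnings.warn("resultant length ~ 0: mean direction undefined")
        mean = float("nan")
        r = 0.0 if r < 1e-15 else r
    else:
        mean = float(np.rad2deg(np.angle(z)) % 360.0)
    return CircularSample(angles=a, mean_direction=mean, r=min(r, 1.0))


def rayleigh_test(sample: CircularSample | np.ndarray) -> tuple[float, float]:
    """Rayleigh's test of uniformity: z = n * r**2 and the standard
    finite-sample approximation

        p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)),   R = n * r.
    """
    if not isinstance(sample, CircularSample):
        sample = circ_mean_r(sample)
    n, r = sample.n, sample.r
    if n == 0:
        raise ValueError("empty sample")
    if n < 4:
        warnings.warn("Rayleigh test with n < 4 is unreliable")
    R = n * r
    z = n * r**2
    p = float(np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2 * n)))
    return float(z), min(p, 1.0)


def _a1inv(rbar: float) -> float:
    """Inverse of A1(kappa) = I1(kappa)/I0(kappa): ML estimate of the von
    Mises concentration from a mean resultant length (Fisher 1993)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups: list[CircularSample | np.ndarray]) -> tuple[float, float]:
    """Watson-Williams test for equal mean directions across groups.

    F = K * (N - k)(sum R_i - R) / ((k - 1)(N - sum R_i)) with the
    concentration correction K = 1 + 3/(8 kappa_hat); p from F(k-1, N-k).
    Warns when the common-concentration assumption is doubtful
    (weighted mean resultant length < 0.45 or groups with n < 5).
    """
    samples = [
        s if isinstance(s, CircularSample) else circ_mean_r(s) for s in groups
    ]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.n < 2 for s in samples):
        raise ValueError("each group needs at least two angles")
    if any(s.n < 5 for s in samples):
        warnings.warn("Watson-Williams with group n < 5 is unreliable")
    k = len(samples)
    n_i = np.array([s.n for s in samples], dtype=float)
    R_i = np.array([s.n * s.r for s in samples])
    N = n_i.sum()
    pooled = circ_mean_r(np.concatenate([s.angles for s in samples]))
    R = N * pooled.r
    rw = R_i.sum() / N
    if rw < 0.45:
        warnings.warn(
            "Watson-Williams assumptions doubtful: weighted mean resultant "
            f"length {rw:.2f} < 0.45"
        )
    denom = N - R_i.sum()
    if denom <= 1e-12:
        raise ValueError(
            "degenerate Watson-Williams denominator: all angles identical "
            "within every group"
        )
    kappa = _a1inv(rw)
    K = 1.0 + 3.0 / (8.0 * kappa)
    F = K * ((N - k) * (R_i.sum() - R)) / ((k - 1) * denom)
    F = max(float(F), 0.0)
    p = float(stats.f.sf(F, k - 1, N - k))
    return F, p


def per_subject_means(samples: list[CircularSample | np.ndarray]) -> CircularSample:
    """Group-level circular sample: one circular mean per subject.

    Mirrors the two analysis levels used for coordination data: per-subject
    analyses use raw cycles, group analyses first average the cycles of
    each subject (7-21 cycles each) and then treat subject means as the
    sample.
    """
    means = []
    for s in samples:
        cs = s if isinstance(s, CircularSample) else circ_mean_r(s)
        means.append(cs.mean_direction)
    return circ_mean_r(np.asarray(means))


def coupling_summary(angles_by_condition: dict[str, np.ndarray]) -> dict:
    """Mean direction, r, Rayleigh z/p per condition plus the pairwise
    Watson-Williams p-matrix between conditions."""
    out: dict = {"conditions": {}, "watson_williams_p": {}}
    samples = {}
    for cond, ang in angles_by_condition.items():
        cs = circ_mean_r(ang)
        z, p = rayleigh_test(cs)
        samples[cond] = cs
        out["conditions"][cond] = {
            "n": cs.n,
            "mean_direction_deg": cs.mean_direction,
            "r": cs.r,
            "rayleigh_z": z,
            "rayleigh_p": p,
        }
    conds = list(angles_by_condition)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            try:
                _, p = watson_williams([samples[a], samples[b]])
            except ValueError:
                p = float("nan")
            out["watson_williams_p"][f"{a}|{b}"] = p
    return out
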