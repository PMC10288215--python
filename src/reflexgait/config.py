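"""Study configuration: locomotor conditions, muscle set, stimulation protocol.

The four locomotor conditions are tied-belt locomotion at two speeds
(``tied_slow`` 0.4/0.4 m/s, ``tied_fast`` 0.8/0.8 m/s) and split-belt
locomotion with a 0.4 m/s left-right speed difference (``split_slow``:
reference/left side on the slow belt; ``split_fast``: reference side on the
fast belt).  Defaults throughout model treadmill locomotion in the adult
cat: cycle duration shortens with the mean belt speed, the stance fraction
(duty factor) shortens with the speed of the belt under the limb, and
cutaneous nerve stimulation is delivered as short trains (three 0.2 ms
pulses at 300 Hz, 1.2x motor threshold) every 2-4 locomotor cycles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

LIMBS = ("LF", "RF", "LH", "RH")
FORELIMBS = ("LF", "RF")
HINDLIMBS = ("LH", "RH")

#: limb couplings -> (reference limb, other limb).  The reference limb is the
#: left forelimb except for the homologous hindlimb coupling (left hindlimb).
COUPLINGS = {
    "forelimb": ("LF", "RF"),
    "hindlimb": ("LH", "RH"),
    "homolateral": ("LF", "LH"),
    "diagonal": ("LF", "RH"),
}

#: couplings for which spatial (gap) intervals are defined
GAP_COUPLINGS = ("forelimb", "hindlimb")

CONDITIONS = ("tied_slow", "tied_fast", "split_slow", "split_fast")

#: left/right belt speeds (m/s) per condition
CONDITION_SPEEDS = {
    "tied_slow": (0.4, 0.4),
    "tied_fast": (0.8, 0.8),
    "split_slow": (0.4, 0.8),
    "split_fast": (0.8, 0.4),
}

# Temporal coupling targets: (circular mean, deg; von Mises concentration).
# Tied-belt gait alternates homologous limbs (~180 deg); the lateral-walk
# footfall sequence puts the homolateral coupling near 90 deg.  Split-belt
# shifts phasing modestly and raises step-by-step dispersion; tied_fast is
# the tightest (largest kappa), matching the ordering of dispersion reported
# for cats across these conditions.  Diagonal targets are kept consistent
# with homolateral + hindlimb so the realized couplings close around the
# four limbs.
PHASE_TARGETS = {
    "tied_slow": {
        "forelimb": (180.0, 25.0),
        "hindlimb": (180.0, 25.0),
        "homolateral": (90.0, 25.0),
        "diagonal": (270.0, 25.0),
    },
    "tied_fast": {
        "forelimb": (180.0, 50.0),
        "hindlimb": (180.0, 50.0),
        "homolateral": (90.0, 50.0),
        "diagonal": (270.0, 50.0),
    },
    "split_slow": {
        "forelimb": (170.0, 15.0),
        "hindlimb": (170.0, 15.0),
        "homolateral": (75.0, 15.0),
        "diagonal": (245.0, 15.0),
    },
    "split_fast": {
        "forelimb": (190.0, 15.0),
        "hindlimb": (190.0, 15.0),
        "homolateral": (105.0, 15.0),
        "diagonal": (295.0, 15.0),
    },
}

# Spatial coupling targets (homologous pairs only).  Tied-belt gait places
# the trailing paw half a stride behind the leading one (180 deg); split-belt
# shifts the homologous contact point to ~270 deg (reference on the slow
# belt) or ~90 deg (reference on the fast belt), mirror images of each other.
# Spatial dispersion is widest during split-belt locomotion (smallest kappa).
GAP_TARGETS = {
    "tied_slow": {"forelimb": (180.0, 8.0), "hindlimb": (180.0, 8.0)},
    "tied_fast": {"forelimb": (180.0, 12.0), "hindlimb": (180.0, 12.0)},
    "split_slow": {"forelimb": (270.0, 4.0), "hindlimb": (270.0, 4.0)},
    "split_fast": {"forelimb": (90.0, 4.0), "hindlimb": (90.0, 4.0)},
}


@dataclass(frozen=True)
class MuscleSpec:
    """One EMG channel: a muscle, its limb, and its activity window.

    ``window`` is the burst support as a fraction of the limb's own
    contact-to-contact cycle (extensors burst through stance from contact,
    flexors through swing); ``peak`` is the burst amplitude in arbitrary
    units.
    """

    name: str
    limb: str
    window: tuple[float, float]
    peak: float = 1.0

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}")
        a, b = self.window
        if not (0.0 <= a < b <= 1.0):
            raise ValueError(f"activity window {self.window} not inside [0, 1]")


@dataclass(frozen=True)
class StimSpec:
    """Cutaneous nerve stimulation protocol (train spec and scheduling)."""

    nerve: str = "SP"
    limb: str = "LH"
    n_pulses: int = 3
    pulse_width_ms: float = 0.2
    rate_hz: float = 300.0
    intensity_mt: float = 1.2
    gap_cycles: tuple[int, int] = (2, 4)

    def __post_init__(self) -> None:
        lo, hi = self.gap_cycles
        if not (2 <= lo <= hi <= 4):
            raise ValueError("cycles-between-stimuli range must lie within [2, 4]")
        if self.limb not in LIMBS:
            raise ValueError(f"unknown stimulated limb {self.limb!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Variability of the synthetic session.

    duration_cv    step-by-step CV of cycle duration
    stance_cv      CV of stance duration
    contact_x_sd   SD (m) of paw placement on the reference side
    mult           multiplicative EMG envelope noise (relative SD)
    additive       additive EMG noise SD (a.u.)
    """

    duration_cv: float = 0.03
    stance_cv: float = 0.02
    contact_x_sd: float = 0.005
    mult: float = 0.15
    additive: float = 0.02

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(*(factor * v for v in dataclasses.astuple(self)))


#: default recorded muscles.  SRT (hip flexor) on the stimulated hindlimb is
#: the conventional cycle-reference muscle; SOL/TA cover the stimulated limb
#: (homonymous), right SOL the crossed hindlimb, ECU the homolateral forelimb.
DEFAULT_MUSCLES = (
    MuscleSpec("SRT", "LH", (0.60, 0.95), 0.8),
    MuscleSpec("SOL", "LH", (0.02, 0.60), 1.0),
    MuscleSpec("TA", "LH", (0.62, 0.92), 0.9),
    MuscleSpec("SOL", "RH", (0.02, 0.60), 1.0),
    MuscleSpec("ECU", "LF", (0.05, 0.55), 0.9),
)


@dataclass
class SessionConfig:
    """Everything needed to synthesize one locomotor session.

    ``cycle_duration_model`` maps the mean belt speed v (m/s) to the mean
    cycle duration a + b*v (s); ``stance_fraction_model`` maps the limb's own
    belt speed to its duty factor.  Defaults give 1.0 s cycles at 0.4 m/s and
    0.7 s at 0.8 m/s with duty factors of 0.63 and 0.54, in the range
    reported for cats at these speeds, and reproduce the ordering
    tied_slow > split > tied_fast for cycle duration.
    """

    condition: str = "tied_slow"
    left_speed: float = 0.4
    right_speed: float = 0.4
    n_cycles: int = 120
    emg_sample_rate: float = 5000.0
    cycle_duration_model: tuple[float, float] = (1.30, -0.75)
    stance_fraction_model: tuple[float, float] = (0.72, -0.22)
    phase_targets: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    gap_targets: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    muscles: tuple[MuscleSpec, ...] = DEFAULT_MUSCLES
    stim: StimSpec = field(default_factory=StimSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    tone: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.left_speed <= 0 or self.right_speed <= 0:
            raise ValueError("belt speeds must be positive")
        if self.n_cycles < 20:
            raise ValueError("need at least 20 locomotor cycles")
        if self.emg_sample_rate < 1000.0:
            raise ValueError(
                "EMG sample rate must be >= 1000 Hz (reflex windows are 7-60 ms)"
            )
        if not self.phase_targets:
            self.phase_targets = dict(PHASE_TARGETS[self.condition])
        if not self.gap_targets:
            self.gap_targets = dict(GAP_TARGETS[self.condition])
        for v in (self.left_speed, self.right_speed):
            a, b = self.stance_fraction_model
            frac = a + b * v
            if not (0.0 < frac < 1.0):
                raise ValueError(
                    f"stance fraction {frac:.3f} at belt speed {v} m/s is not in (0, 1)"
                )
        a, b = self.cycle_duration_model
        if a + b * self.mean_speed <= 0:
            raise ValueError("cycle-duration model gives a non-positive duration")

    @property
    def mean_speed(self) -> float:
        return 0.5 * (self.left_speed + self.right_speed)

    def belt_speed(self, limb: str) -> float:
        return self.left_speed if limb.startswith("L") else self.right_speed

    def cycle_duration(self) -> float:
        a, b = self.cycle_duration_model
        return a + b * self.mean_speed

    def stance_fraction(self, limb: str) -> float:
        a, b = self.stance_fraction_model
        return a + b * self.belt_speed(limb)


def condition_config(condition: str, seed: int = 0, **overrides) -> SessionConfig:
    """A :class:`SessionConfig` preset for one of the four conditions."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; choose from {CONDITIONS}")
    left, right = CONDITION_SPEEDS[condition]
    return SessionConfig(
        condition=condition, left_speed=left, right_speed=right, seed=seed, **overrides
    )


def noiseless_config(condition: str, seed: int = 0, **overrides) -> SessionConfig:
    """A deterministic session: every noise source off and every coupling
    pinned exactly at its target (infinite concentration).  Useful as the
    noise-free limit for recovery and invariance checks."""
    base = condition_config(condition, seed=seed)
    overrides.setdefault("noise", NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0))
    overrides.setdefault(
        "phase_targets", {k: (m, float("inf")) for k, (m, _) in base.phase_targets.items()}
    )
    overrides.setdefault(
        "gap_targets", {k: (m, float("inf")) for k, (m, _) in base.gap_targets.items()}
    )
    return condition_config(condition, seed=seed, **overrides)


@dataclass
class AnalysisConfig:
    """Parameters of the reflex analysis.

    Latency windows (ms post-stimulus) define the response classes: short
    (P1/N1, 7-18 ms), mid (P2/N2, 19-34 ms) and long (P3/N3, 35-60 ms);
    interlimb responses with onsets <= 18 ms are short-latency by the
    spino-bulbo-spinal argument (minimal supraspinal loop latency in the cat
    is 18 ms).  Detection uses a pointwise two-sided confidence band at
    ``ci_level`` built from phase-matched control cycles; a deflection must
    stay outside the band for ``min_duration_ms`` to count as a response.
    """

    n_bins: int = 10
    latency_windows: tuple[tuple[float, float], ...] = ((7.0, 18.0), (19.0, 34.0), (35.0, 60.0))
    interlimb_short_cap_ms: float = 18.0
    ci_level: float = 97.5
    min_stimuli: int = 4
    min_duration_ms: float = 3.0
    smooth_ms: float = 2.0
    search_window_ms: tuple[float, float] = (7.0, 60.0)
    trace_window_ms: float = 80.0
    reference_limb: str = "LH"
    reference_muscle: str = "SRT"
    n_norm_points: int = 200
    max_control_segments: int = 300
    band_floor_frac: float = 1e-4
    normalization: str = "signed_max"  # or "abs_max"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (50.0 < self.ci_level < 100.0):
            raise ValueError("CI level must lie in (50, 100)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        w = self.latency_windows
        if any(a >= b for a, b in w) or any(
            w[i][1] >= w[i + 1][0] for i in range(len(w) - 1)
        ):
            raise ValueError("latency windows must be ordered and non-overlapping")
        if self.normalization not in ("signed_max", "abs_max"):
            raise ValueError("normalization must be 'signed_max' or 'abs_max'")


def limb_relation(muscle_limb: str, stim_limb: str) -> str:
    """homonymous / crossed / homolateral / diagonal, relative to the
    stimulated limb."""
    if muscle_limb == stim_limb:
        return "homonymous"
    same_side = muscle_limb[0] == stim_limb[0]
    same_girdle = muscle_limb[1] == stim_limb[1]
    if same_girdle:
        return "crossed"
    return "homolateral" if same_side else "diagonal"
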