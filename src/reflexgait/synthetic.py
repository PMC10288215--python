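"""Synthetic four-limb locomotor sessions with known ground truth.

The generator emulates a cat on a split-belt treadmill: rhythmic contact/
liftoff events for the four limbs whose cycle durations, duty factors and
pairwise phase/gap couplings follow the configured condition targets (von
Mises step-by-step dispersion); burst-like rectified EMG envelopes per
muscle; cutaneous-nerve stimulus trains delivered every 2-4 cycles at
uniformly distributed within-cycle delays; and evoked reflex responses
injected as smooth raised-cosine bumps at configurable latencies whose
signed amplitude follows a 10-phase modulation profile.

The injected bump amplitude is ``profile[phase bin] x`` (mean clean
rectified envelope over the bump support): a multiplicative reflex-gain
model in which the evoked response scales with the background excitability
of the motor pool.  Dividing the evoked integral by the baseline locomotor
EMG - the core normalization of the analysis - therefore recovers the
injected profile itself, which is what makes end-to-end parameter-recovery
testing possible.

Every random draw comes from one seeded generator, so identical configs and
seeds give bit-identical sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import LIMBS, SessionConfig, limb_relation
from .kinematics import GaitEventSeries

#: resting x position (m) of each paw in the treadmill frame
_BASE_X = {"LF": 0.25, "RF": 0.25, "LH": -0.10, "RH": -0.10}

_LATENCY_WINDOWS = ((7.0, 18.0), (19.0, 34.0), (35.0, 60.0))


@dataclass(frozen=True)
class ResponseSpec:
    """One injected evoked response: muscle channel, onset latency and
    duration (ms post-stimulus), and its signed amplitude profile over the
    10 phase bins (arbitrary gain units; positive = excitatory)."""

    muscle: str
    limb: str
    onset_ms: float
    duration_ms: float
    profile: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.profile) != 10:
            raise ValueError("amplitude profile must have 10 phase-bin values")
        if not any(lo <= self.onset_ms <= hi for lo, hi in _LATENCY_WINDOWS):
            raise ValueError(
                f"onset {self.onset_ms} ms outside the latency class windows "
                f"{_LATENCY_WINDOWS}"
            )

    def latency_class(self, sign: int) -> str:
        letter = "P" if sign > 0 else "N"
        for i, (lo, hi) in enumerate(_LATENCY_WINDOWS, start=1):
            if lo <= self.onset_ms <= hi:
                return f"{letter}{i}"
        raise AssertionError("unreachable: onset validated at construction")


#: default injected responses for left-SP stimulation: homonymous short-
#: latency responses in TA (excitatory during swing) and SOL (inhibitory
#: during its stance activity, excitatory during its inactive phases),
#: a crossed mid-latency response in right SOL and a homolateral long-
#: latency response in ECU.  Onsets sit at the centers of the three latency
#: class windows.
DEFAULT_RESPONSES = (
    ResponseSpec("TA", "LH", 12.0, 10.0, (0, 0, 0, 0, 0, 0.2, 0.6, 1.0, 0.8, 0.3)),
    ResponseSpec(
        "SOL", "LH", 12.0, 10.0, (-0.3, -0.3, -0.25, -0.2, -0.1, 0, 0.5, 0.8, 0.6, 0.2)
    ),
    ResponseSpec("SOL", "RH", 26.0, 12.0, (0.2, 0, 0, 0.1, 0.3, 0.5, 0.8, 0.6, 0.4, 0.3)),
    ResponseSpec("ECU", "LF", 47.0, 14.0, (0.3, 0.5, 0.7, 0.6, 0.4, 0.2, 0, 0, 0.1, 0.2)),
)


@dataclass
class ReflexGroundTruth:
    """Hidden parameters of a generated session, for recovery testing."""

    responses: tuple[ResponseSpec, ...]
    phase_targets: dict
    gap_targets: dict
    reference_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    stim_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    truncated_stims: tuple[int, ...] = ()

    def response_for(self, muscle: str, limb: str) -> ResponseSpec | None:
        for r in self.responses:
            if r.muscle == muscle and r.limb == limb:
                return r
        return None


@dataclass
class EmgRecording:
    """Sampled multi-channel rectified-EMG-like activity with stimulus
    event times.  ``channels`` pairs each row of ``data`` with its
    (muscle, limb)."""

    data: np.ndarray
    rate: float
    channels: tuple[tuple[str, str], ...]
    stim_times: np.ndarray
    nerve: str = "SP"
    stim_limb: str = "LH"

    def __post_init__(self) -> None:
        if self.rate < 1000.0:
            raise ValueError("EMG sample rate must be >= 1000 Hz")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EMG samples must be finite")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate

    def channel(self, muscle: str, limb: str | None = None) -> np.ndarray:
        for i, (name, lb) in enumerate(self.channels):
            if name == muscle and (limb is None or lb == limb):
                return self.data[i]
        raise KeyError(f"no channel {muscle!r} (limb={limb!r})")


@dataclass
class SessionBundle:
    """One generated or loaded session: gait events for the four limbs,
    the EMG recording with its stimulus train, and the configuration.
    ``ground_truth`` is present only for synthetic sessions."""

    config: SessionConfig
    gait_events: dict[str, GaitEventSeries]
    emg: EmgRecording
    ground_truth: ReflexGroundTruth | None = None

    def validate(self) -> None:
        for limb in LIMBS:
            if limb not in self.gait_events:
                raise ValueError(f"missing gait events for limb {limb}")
            self.gait_events[limb].validate()
        t = self.emg.stim_times
        if t.size and (t.min() < 0 or t.max() > self.emg.duration):
            raise ValueError("stimulation times fall outside the EMG recording")


# ---------------------------------------------------------------------------
# gait events

def _draw_angles(rng, mean_deg: float, kappa: float, n: int) -> np.ndarray:
    """Von Mises draws in degrees around ``mean_deg`` (kappa = inf -> exact).

    Draws are centered on zero and shifted, so a target near 180 deg cannot
    wrap to -180 deg and reorder the contact sequence.
    """
    if not np.isfinite(kappa):
        return np.full(n, float(mean_deg))
    return mean_deg + np.rad2deg(rng.vonmises(0.0, kappa, size=n))


def generate_gait_events(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> dict[str, GaitEventSeries]:
    """Contact/liftoff sequences for the four limbs realizing the
    configured cycle-duration, duty-factor and coupling targets.

    The left forelimb is the master oscillator; the right forelimb and left
    hindlimb are placed by the forelimb/homolateral phase draws, the right
    hindlimb by the hindlimb phase draw relative to the left hindlimb.  Paw
    contact positions on the right side are solved so the realized gap
    intervals match the per-cycle gap draws; during stance every paw rides
    its belt backward, so stride length equals belt speed x cycle duration
    at steady state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cycles
    m = n + 3  # LF contacts (extra cycles trimmed after derivation)
    t_mean = config.cycle_duration()
    noise = config.noise

    durs = t_mean * (1.0 + noise.duration_cv * rng.standard_normal(m - 1))
    durs = np.clip(durs, 0.3 * t_mean, 2.0 * t_mean)
    c_lf = 0.5 + np.concatenate(([0.0], np.cumsum(durs)))

    th_fore = _draw_angles(rng, *config.phase_targets["forelimb"], m - 1)
    th_homo = _draw_angles(rng, *config.phase_targets["homolateral"], m - 1)
    th_hind = _draw_angles(rng, *config.phase_targets["hindlimb"], m - 2)

    c_rf = c_lf[:-1] + th_fore / 360.0 * durs
    c_lh = c_lf[:-1] + th_homo / 360.0 * durs
    c_rh = c_lh[:-1] + th_hind / 360.0 * np.diff(c_lh)

    contacts = {"LF": c_lf, "RF": c_rf, "LH": c_lh, "RH": c_rh}
    stance, liftoffs = {}, {}
    for limb in LIMBS:
        c = contacts[limb]
        d = np.diff(c)
        frac = config.stance_fraction(limb) * (
            1.0 + noise.stance_cv * rng.standard_normal(len(d))
        )
        st = np.clip(frac, 0.1, 0.9) * d
        stance[limb] = st
        liftoffs[limb] = c[:-1] + st

    # reference-side contact positions; trailing-side positions solved below
    x_contact = {}
    for limb in LIMBS:
        c = contacts[limb]
        x_contact[limb] = _BASE_X[limb] + noise.contact_x_sd * rng.standard_normal(len(c))

    # Realize the homologous gap draws exactly by placing the REFERENCE
    # limb's contact positions: each reference contact constrains only its
    # own position (strides depend on belt travel, not placement), so the
    # per-cycle draw g_i is met exactly via
    #   x_ref_i = x_trailing(t_contact_i) + (g_i / 360) * stride_ref_i.
    for pair, (ref_limb, other) in (("forelimb", ("LF", "RF")), ("hindlimb", ("LH", "RH"))):
        mean_g, kappa_g = config.gap_targets[pair]
        c_ref, c_oth = contacts[ref_limb], contacts[other]
        gaps = np.mod(_draw_angles(rng, mean_g, kappa_g, len(c_ref) - 1), 360.0)
        belt_ref = config.belt_speed(ref_limb)
        belt_oth = config.belt_speed(other)
        st_oth = stance[other]
        lo_oth = liftoffs[other]
        for i in range(len(c_ref) - 1):
            t_c = c_ref[i]
            j = int(np.searchsorted(c_oth, t_c, side="right")) - 1
            if j < 0 or j >= len(st_oth):
                continue
            if t_c <= lo_oth[j]:  # trailing limb in stance
                x_t = x_contact[other][j] - belt_oth * (t_c - c_oth[j])
            elif j + 1 < len(c_oth):  # trailing limb in swing
                lx = x_contact[other][j] - belt_oth * st_oth[j]
                frac = (t_c - lo_oth[j]) / (c_oth[j + 1] - lo_oth[j])
                x_t = lx + frac * (x_contact[other][j + 1] - lx)
            else:
                continue
            stride_ref = belt_ref * (c_ref[i + 1] - c_ref[i])
            x_contact[ref_limb][i] = x_t + gaps[i] / 360.0 * stride_ref

    series = {}
    for limb in LIMBS:
        c = contacts[limb][: n + 1]
        series[limb] = GaitEventSeries(
            limb=limb,
            contact_times=c,
            liftoff_times=liftoffs[limb][:n],
            contact_x=x_contact[limb][: n + 1],
            liftoff_x=x_contact[limb][:n] - config.belt_speed(limb) * stance[limb][:n],
            belt_speed=config.belt_speed(limb),
        )
    return series


# ---------------------------------------------------------------------------
# stimulus train

def generate_stim_times(
    config: SessionConfig,
    gait_events: dict[str, GaitEventSeries],
    rng: np.random.Generator | None = None,
    reference_limb: str | None = None,
) -> np.ndarray:
    """Stimulus times: one stimulus every 2-4 cycles (uniform over {2,3,4})
    of the reference limb, at a delay uniform over the cycle, so that all
    10 phase bins are populated.  Times are snapped to the EMG sample grid
    (the stimulator is triggered by the acquisition clock)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = gait_events[reference_limb or config.stim.limb]
    onsets = ref.contact_times
    lo, hi = config.stim.gap_cycles
    times = []
    i = int(rng.integers(lo, hi + 1))
    while i < len(onsets) - 1:
        dur = onsets[i + 1] - onsets[i]
        t = onsets[i] + rng.uniform() * dur
        times.append(round(t * config.emg_sample_rate) / config.emg_sample_rate)
        i += int(rng.integers(lo, hi + 1))
    return np.asarray(times)


# ---------------------------------------------------------------------------
# EMG

def window_samples(rate: float, start_ms: float, stop_ms: float) -> tuple[int, int]:
    """Inclusive sample-offset range [k0, k1] covering a post-stimulus
    window in ms.  Shared by the generator and the analyzer so that
    injected and integrated windows coincide exactly."""
    k0 = int(round(start_ms * rate / 1000.0))
    k1 = int(round(stop_ms * rate / 1000.0))
    if k1 <= k0:
        raise ValueError("empty window")
    return k0, k1


def _clean_envelope(
    config: SessionConfig, events: dict[str, GaitEventSeries], n_samples: int
) -> np.ndarray:
    """Deterministic rectified envelopes (tone + per-cycle raised-cosine
    bursts), one row per muscle."""
    fs = config.emg_sample_rate
    env = np.full((len(config.muscles), n_samples), config.tone)
    for ch, spec in enumerate(config.muscles):
        ev = events[spec.limb]
        # extrapolate one cycle on each side: the animal is in steady-state
        # locomotion, so the EMG must not fall silent at the event-window
        # edges (limb event spans are staggered across limbs)
        c = ev.contact_times
        c = np.concatenate(([c[0] - (c[1] - c[0])], c, [c[-1] + (c[-1] - c[-2])]))
        for i in range(len(c) - 1):
            d = c[i + 1] - c[i]
            a = c[i] + spec.window[0] * d
            b = c[i] + spec.window[1] * d
            i0, i1 = int(np.ceil(a * fs)), int(np.floor(b * fs))
            i0, i1 = max(i0, 0), min(i1, n_samples - 1)
            if i1 <= i0:
                continue
            t = np.arange(i0, i1 + 1) / fs
            env[ch, i0 : i1 + 1] += spec.peak * (
                0.5 - 0.5 * np.cos(2 * np.pi * (t - a) / (b - a))
            )
    return env


def assign_bins(
    stim_times: np.ndarray, onsets: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Phase bin (0..n_bins-1) of each stimulus within the reference cycle
    containing it; -1 for stimuli outside the cycle span."""
    bins = np.full(len(stim_times), -1, dtype=int)
    for s, t in enumerate(stim_times):
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        if i < 0 or i >= len(onsets) - 1:
            continue
        u = (t - onsets[i]) / (onsets[i + 1] - onsets[i])
        bins[s] = min(int(n_bins * u), n_bins - 1)
    return bins


def generate_emg(
    config: SessionConfig,
    gait_events: dict[str, GaitEventSeries],
    stim_times: np.ndarray,
    responses: tuple[ResponseSpec, ...] = DEFAULT_RESPONSES,
    rng: np.random.Generator | None = None,
) -> tuple[EmgRecording, ReflexGroundTruth]:
    """Burst-envelope EMG per muscle with injected evoked responses.

    Each channel is envelope x (1 + multiplicative noise) + additive noise
    + evoked bumps, clipped at zero (the signal stands for full-wave
    rectified EMG, so inhibition can at most silence it).  Each bump is a
    raised cosine starting ``onset_ms`` after the stimulus, lasting
    ``duration_ms``, with amplitude profile[bin] x local clean-envelope
    mean; bumps running past the end of the recording are truncated and
    flagged in the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.emg_sample_rate
    end = max(ev.contact_times[-1] for ev in gait_events.values()) + 0.5
    n_samples = int(round(end * fs))

    env = _clean_envelope(config, gait_events, n_samples)
    onsets = gait_events[config.stim.limb].contact_times
    bins = assign_bins(stim_times, onsets)

    bumps = np.zeros_like(env)
    truncated: list[int] = []
    resp_by_channel = {
        ch: next(
            (r for r in responses if r.muscle == spec.name and r.limb == spec.limb),
            None,
        )
        for ch, spec in enumerate(config.muscles)
    }
    for s, t in enumerate(stim_times):
        if bins[s] < 0:
            continue
        i_s = int(round(t * fs))
        for ch, resp in resp_by_channel.items():
            if resp is None:
                continue
            amp_gain = resp.profile[bins[s]]
            if amp_gain == 0.0:
                continue
            k0, k1 = window_samples(fs, resp.onset_ms, resp.onset_ms + resp.duration_ms)
            i0, i1 = i_s + k0, i_s + k1
            if i0 >= n_samples:
                truncated.append(s)
                continue
            if i1 >= n_samples:
                truncated.append(s)
            j1 = min(i1, n_samples - 1)
            local = np.trapezoid(env[ch, i0 : i1 + 1][: j1 - i0 + 1]) / (k1 - k0)
            kernel = 0.5 - 0.5 * np.cos(
                2 * np.pi * np.arange(j1 - i0 + 1) / (i1 - i0)
            )
            bumps[ch, i0 : j1 + 1] += amp_gain * local * kernel

    noise = config.noise
    data = env * (1.0 + noise.mult * rng.standard_normal(env.shape))
    data += noise.additive * rng.standard_normal(env.shape)
    data = np.maximum(data + bumps, 0.0)

    emg = EmgRecording(
        data=data,
        rate=fs,
        channels=tuple((m.name, m.limb) for m in config.muscles),
        stim_times=np.asarray(stim_times, dtype=float),
        nerve=config.stim.nerve,
        stim_limb=config.stim.limb,
    )
    truth = ReflexGroundTruth(
        responses=tuple(responses),
        phase_targets=dict(config.phase_targets),
        gap_targets=dict(config.gap_targets),
        reference_onsets=onsets.copy(),
        stim_bins=bins,
        truncated_stims=tuple(sorted(set(truncated))),
    )
    return emg, truth


def generate_session(
    config: SessionConfig,
    responses: tuple[ResponseSpec, ...] = DEFAULT_RESPONSES,
) -> SessionBundle:
    """Full synthetic session (events, stimulus train, EMG, ground truth)
    from one seeded random stream."""
    for r in responses:
        if not any(m.name == r.muscle and m.limb == r.limb for m in config.muscles):
            warnings.warn(
                f"response spec for {r.muscle}/{r.limb} has no matching EMG channel"
            )
    rng = np.random.default_rng(config.seed)
    events = generate_gait_events(config, rng)
    stims = generate_stim_times(config, events, rng)
    emg, truth = generate_emg(config, events, stims, responses, rng)
    bundle = SessionBundle(config=config, gait_events=events, emg=emg, ground_truth=truth)
    bundle.validate()
    return bundle
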