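"""Phase- and task-dependent quantification of cutaneous reflex responses.

The analysis follows the classical stimulus-triggered averaging scheme:

1. Locomotor cycles (successive reference onsets) are tagged stimulated,
   control, or excluded (a cycle following a stimulated one is excluded so
   long-latency aftereffects cannot contaminate the baseline).
2. Control cycles, full-wave rectified and time-normalized, are averaged
   into the baseline locomotor EMG (blEMG) with 10 equal phase bins; the
   blEMG indexes the excitability of the motor pool across the cycle.
3. Stimulated cycles are grouped into 10 phase bins by the within-cycle
   time of their stimulus.  For each bin, the average rectified trace after
   the stimulus is compared with phase-matched control segments; a
   deflection that leaves the pointwise 97.5% confidence band of the
   controls for a minimum duration is a response.  Onset latency classifies
   it as P1/N1 (7-18 ms), P2/N2 (19-34 ms) or P3/N3 (35-60 ms); responses
   in non-stimulated limbs with onsets <= 18 ms are short-latency (the
   minimal spino-bulbo-spinal latency in the cat is 18 ms).
4. The net reflex value is (integrated stimulated trace - integrated
   blEMG) / integrated blEMG over the response window, so excitation is
   positive, inhibition negative, and changes in background excitability
   cancel (doubling every trace leaves the value unchanged).
5. Responses are normalized per muscle to the maximal value across the
   four locomotor conditions (percent); the modulation index of a
   condition is the largest minus the smallest normalized response over
   its 10 phases, and exceeds 100% when responses change sign across
   phases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .config import AnalysisConfig, limb_relation
from .synthetic import EmgRecording, assign_bins, window_samples

log = logging.getLogger(__name__)

FAMILY_OF_CLASS = {"P1": "short", "N1": "short", "P2": "mid", "N2": "mid", "P3": "long", "N3": "long"}


# ---------------------------------------------------------------------------
# cycle bookkeeping

def tag_cycles(onsets: np.ndarray, stim_times: np.ndarray) -> np.ndarray:
    """Label each cycle [onset_i, onset_{i+1}) as stimulated ('S'),
    control ('C': no stimulus and not preceded by a stimulated cycle),
    or excluded ('X')."""
    onsets = np.asarray(onsets, dtype=float)
    stim = np.asarray(stim_times, dtype=float)
    n = len(onsets) - 1
    labels = np.empty(n, dtype="<U1")
    prev_stimulated = False
    for i in range(n):
        has = bool(np.any((stim >= onsets[i]) & (stim < onsets[i + 1])))
        if has:
            labels[i] = "S"
        elif prev_stimulated:
            labels[i] = "X"
        else:
            labels[i] = "C"
        prev_stimulated = has
    return labels


def assign_stim_phase(stim_time: float, onset: float, duration: float, n_bins: int = 10) -> int:
    """Phase bin of a stimulus within its cycle (floor, clamped to the
    last bin)."""
    if not (onset <= stim_time < onset + duration):
        raise ValueError("stimulus lies outside the cycle")
    return min(int(n_bins * (stim_time - onset) / duration), n_bins - 1)


# ---------------------------------------------------------------------------
# baseline locomotor EMG

@dataclass
class BaselineProfile:
    """Mean rectified control-cycle EMG of one muscle: the time-normalized
    average trace, its 10 phase-bin means, and the control-cycle count."""

    muscle: str
    limb: str
    trace: np.ndarray
    bin_means: np.ndarray
    n_control: int
    condition: str = ""


def _normalized_cycles(
    x: np.ndarray, rate: float, onsets: np.ndarray, idx: np.ndarray, n_points: int
) -> np.ndarray:
    """Rectified cycles resampled to ``n_points`` of normalized time."""
    out = np.empty((len(idx), n_points))
    u = np.arange(n_points) / n_points
    t_axis = np.arange(len(x)) / rate
    for row, i in enumerate(idx):
        t = onsets[i] + u * (onsets[i + 1] - onsets[i])
        out[row] = np.interp(t, t_axis, np.abs(x))
    return out


def build_blemg(
    x: np.ndarray,
    rate: float,
    onsets: np.ndarray,
    labels: np.ndarray,
    muscle: str = "",
    limb: str = "",
    n_bins: int = 10,
    n_points: int = 200,
) -> BaselineProfile:
    """Average the rectified control cycles in normalized time and bin the
    average into ``n_bins`` equal subphases."""
    ctrl = np.flatnonzero(labels == "C")
    if ctrl.size == 0:
        raise ValueError("no control cycles: cannot build the blEMG")
    if ctrl.size < 10:
        warnings.warn(f"only {ctrl.size} control cycles for blEMG of {muscle}/{limb}")
    cyc = _normalized_cycles(x, rate, onsets, ctrl, n_points)
    trace = cyc.mean(axis=0)
    bin_means = trace.reshape(n_bins, n_points // n_bins).mean(axis=1)
    return BaselineProfile(
        muscle=muscle, limb=limb, trace=trace, bin_means=bin_means, n_control=ctrl.size
    )


def activity_windows(blemg: BaselineProfile, threshold_frac: float = 0.25, half_width: float = 0.075) -> dict:
    """Activity period of a muscle from its blEMG bins, plus the
    mid-activity and mid-inactivity windows (midpoint +/- 7.5% of cycle).

    The activity period is the longest circularly contiguous run of bins
    whose mean exceeds baseline + ``threshold_frac`` x (peak - baseline).
    """
    b = blemg.bin_means
    n = len(b)
    lo, hi = float(b.min()), float(b.max())
    thr = lo + threshold_frac * (hi - lo)
    active = b > thr
    if hi - lo <= 1e-12 or not active.any():
        warnings.warn(f"{blemg.muscle}/{blemg.limb}: no activity above threshold")
        return {"active_bins": [], "activity": None, "mid_activity": None, "mid_inactivity": None}
    if active.all():
        warnings.warn(f"{blemg.muscle}/{blemg.limb}: active over the whole cycle")
        return {"active_bins": list(range(n)), "activity": (0.0, 1.0), "mid_activity": None, "mid_inactivity": None}
    # longest circular run of active bins
    doubled = np.concatenate([active, active])
    best_start, best_len, run = 0, 0, 0
    for i, a in enumerate(doubled):
        run = run + 1 if a else 0
        if a and run > best_len and i - run + 1 < n:
            best_len, best_start = run, i - run + 1
    start_frac = best_start / n
    end_frac = (best_start + best_len) / n
    mid_act = ((start_frac + end_frac) / 2.0) % 1.0
    mid_inact = (mid_act + 0.5 * (1.0 + best_len / n)) % 1.0  # midpoint of the inactive arc
    return {
        "active_bins": [(best_start + k) % n for k in range(best_len)],
        "activity": (start_frac % 1.0, end_frac % 1.0),
        "mid_activity": ((mid_act - half_width) % 1.0, (mid_act + half_width) % 1.0),
        "mid_inactivity": ((mid_inact - half_width) % 1.0, (mid_inact + half_width) % 1.0),
    }


# ---------------------------------------------------------------------------
# stimulus-triggered segments and response detection

def _segments(x: np.ndarray, rate: float, t0: np.ndarray, n_samp: int) -> np.ndarray:
    """Rectified segments of length ``n_samp`` starting at times ``t0``,
    linearly interpolated at exact sample offsets (exact when ``t0`` lies
    on the sample grid)."""
    pos = np.asarray(t0)[:, None] * rate + np.arange(n_samp)[None, :]
    i = np.clip(pos.astype(int), 0, len(x) - 2)
    frac = pos - i
    seg = x[i] * (1.0 - frac) + x[i + 1] * frac
    return np.abs(seg)


@dataclass
class BinTraces:
    """Stimulus-locked averages for one (muscle, phase-bin) cell on a ms
    time axis starting at the stimulus.

    ``stim_mean``/``ctrl_mean`` are the raw rectified averages used for
    integration; ``stim_smooth``/``ctrl_smooth``/``halfwidth`` carry the
    lightly smoothed versions and the confidence band used for response
    detection (smoothing stabilizes the band but would bias integrals near
    sharp envelope transitions, so integration stays on the raw traces).
    """

    muscle: str
    limb: str
    bin: int
    n_stim: int
    n_control_segments: int
    time_ms: np.ndarray
    stim_mean: np.ndarray
    ctrl_mean: np.ndarray
    stim_smooth: np.ndarray
    ctrl_smooth: np.ndarray
    halfwidth: np.ndarray


def stim_triggered_traces(
    x: np.ndarray,
    rate: float,
    stim_times: np.ndarray,
    stim_phases: np.ndarray,
    control_onsets: np.ndarray,
    control_durations: np.ndarray,
    cfg: AnalysisConfig,
    muscle: str = "",
    limb: str = "",
    bin_index: int = -1,
) -> BinTraces:
    """Build the stimulated average and the phase-matched control band for
    one phase bin.

    Control segments are taken at 'virtual stimuli': each control cycle is
    probed at the same within-cycle phases as the real stimuli, so the band
    reflects exactly the background the stimulated average would have had
    without stimulation.  The band is the two-sided ``ci_level`` confidence
    interval of a mean of ``n_stim`` segments (t-based, pointwise, after a
    ``smooth_ms`` moving average), with a small relative floor guarding the
    degenerate noise-free case.
    """
    n_samp = int(round(cfg.trace_window_ms * rate / 1000.0)) + 1
    stim_segs = _segments(x, rate, stim_times, n_samp)

    # probe every control cycle at every stimulus phase; when that exceeds
    # the segment budget, subsample control CYCLES (never phases) so each
    # stimulus phase keeps the same weight in the control average
    n_keep = max(cfg.max_control_segments // max(len(stim_phases), 1), 2)
    if len(control_onsets) > n_keep:
        keep = np.linspace(0, len(control_onsets) - 1, n_keep).astype(int)
        control_onsets = control_onsets[keep]
        control_durations = control_durations[keep]
    virtual = (
        control_onsets[:, None] + stim_phases[None, :] * control_durations[:, None]
    ).ravel()
    ctrl_segs = _segments(x, rate, virtual, n_samp)

    k = max(int(round(cfg.smooth_ms * rate / 1000.0)), 1)
    stim_sm = uniform_filter1d(stim_segs, k, axis=1, mode="nearest")
    ctrl_sm = uniform_filter1d(ctrl_segs, k, axis=1, mode="nearest")

    ctrl_smooth = ctrl_sm.mean(axis=0)
    # variance of the matched average under the null: cycle-to-cycle
    # variability WITHIN each probed phase (the deterministic envelope
    # difference between phases is shared by the stimulated average and
    # must not widen the band)
    by_phase = ctrl_sm.reshape(-1, len(stim_phases), ctrl_sm.shape[1])
    n_ctrl = by_phase.shape[0]
    resid = by_phase - by_phase.mean(axis=0, keepdims=True)
    df = max((n_ctrl - 1) * len(stim_phases), 1)
    sd = np.sqrt((resid**2).sum(axis=(0, 1)) / df)
    tcrit = stats.t.ppf(0.5 + cfg.ci_level / 200.0, df)
    half = tcrit * sd / np.sqrt(len(stim_times))
    half = np.maximum(half, cfg.band_floor_frac * float(ctrl_smooth.max()))
    return BinTraces(
        muscle=muscle,
        limb=limb,
        bin=bin_index,
        n_stim=len(stim_times),
        n_control_segments=ctrl_segs.shape[0],
        time_ms=np.arange(n_samp) / rate * 1000.0,
        stim_mean=stim_segs.mean(axis=0),
        ctrl_mean=ctrl_segs.mean(axis=0),
        stim_smooth=stim_sm.mean(axis=0),
        ctrl_smooth=ctrl_smooth,
        halfwidth=half,
    )


def detect_response(traces: BinTraces, cfg: AnalysisConfig) -> dict | None:
    """Earliest sustained excursion of the stimulated average outside the
    control band within the search window.

    The excursion must persist at least ``min_duration_ms``; its onset is
    the first sample outside the band, its offset the return into the band
    (capped at the end of the trace window), and its sign the side of the
    exit.  Returns None when the stimulated average stays within the band.
    """
    dt_ms = traces.time_ms[1] - traces.time_ms[0]
    min_run = max(int(round(cfg.min_duration_ms / dt_ms)), 1)
    dev = traces.stim_smooth - traces.ctrl_smooth
    outside = np.where(dev > traces.halfwidth, 1, np.where(dev < -traces.halfwidth, -1, 0))
    lo, hi = cfg.search_window_ms
    candidates = np.flatnonzero(
        (traces.time_ms >= lo) & (traces.time_ms <= hi) & (outside != 0)
    )
    for start in candidates:
        sgn = outside[start]
        if start > 0 and outside[start - 1] == sgn:
            continue  # not the start of a run
        end = start
        while end < len(outside) and outside[end] == sgn:
            end += 1
        if end - start >= min_run:
            return {
                "onset_ms": float(traces.time_ms[start]),
                "offset_ms": float(traces.time_ms[min(end, len(outside) - 1)]),
                "sign": int(sgn),
            }
    return None


def classify_response(
    onset_ms: float, sign: int, relation: str, cfg: AnalysisConfig | None = None
) -> tuple[str, bool]:
    """Latency class (P1..N3) of a response; the flag marks onsets falling
    in the unclaimed gaps between the printed windows (assigned to the
    nearer window)."""
    cfg = cfg or AnalysisConfig()
    windows = cfg.latency_windows
    if onset_ms < windows[0][0]:
        raise ValueError(f"onset {onset_ms} ms earlier than {windows[0][0]} ms: stimulus artifact")
    if onset_ms > windows[-1][1]:
        raise ValueError(f"onset {onset_ms} ms beyond the analysis window")
    letter = "P" if sign > 0 else "N"
    if relation != "homonymous" and onset_ms <= cfg.interlimb_short_cap_ms:
        return f"{letter}1", False
    for i, (a, b) in enumerate(windows, start=1):
        if a <= onset_ms <= b:
            return f"{letter}{i}", False
    # onset in a gap between windows: nearer window, flagged
    edges = [w for pair in windows for w in pair]
    nearest = min(range(len(edges)), key=lambda j: abs(edges[j] - onset_ms))
    return f"{letter}{nearest // 2 + 1}", True


def net_reflex_value(
    stim_trace: np.ndarray,
    ctrl_trace: np.ndarray,
    rate: float,
    window_ms: tuple[float, float],
    min_blemg: float = 1e-12,
) -> float:
    """(integrated stimulated - integrated blEMG) / integrated blEMG over
    the response window (trapezoidal); positive = excitation.  NaN (with a
    warning) when the integrated blEMG is below ``min_blemg``."""
    k0, k1 = window_samples(rate, *window_ms)
    k1 = min(k1, len(stim_trace) - 1)
    s = float(np.trapezoid(stim_trace[k0 : k1 + 1]))
    c = float(np.trapezoid(ctrl_trace[k0 : k1 + 1]))
    if c <= min_blemg:
        warnings.warn("integrated blEMG below floor: net reflex value undefined")
        return float("nan")
    return (s - c) / c


# ---------------------------------------------------------------------------
# normalization and modulation

def normalize_responses(values: np.ndarray, mode: str = "signed_max") -> np.ndarray:
    """Express responses as a percentage of the per-muscle maximum across
    all conditions and phases.

    ``signed_max`` (default) divides by the largest signed value, which is
    what lets modulation indexes exceed 100% when inhibitory and excitatory
    responses coexist; ``abs_max`` divides by the largest magnitude.
    NaNs pass through; an all-zero input stays zero.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0 or np.all(finite == 0):
        return np.zeros_like(v)
    if mode == "abs_max":
        denom = float(np.max(np.abs(finite)))
    else:
        denom = float(np.max(finite))
        if denom <= 0:
            warnings.warn(
                "all responses non-positive; normalizing by the largest magnitude"
            )
            denom = float(np.max(np.abs(finite)))
    return v * 100.0 / denom


def modulation_index(normalized_bins: np.ndarray) -> float:
    """Largest minus smallest normalized response over the 10 phases of one
    condition (percent; > 100 when responses change sign across phases).
    NaN when fewer than two phases carry values."""
    v = np.asarray(normalized_bins, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        warnings.warn("fewer than two phases with responses: modulation index undefined")
        return float("nan")
    return float(np.max(finite) - np.min(finite))


# ---------------------------------------------------------------------------
# session-level driver

@dataclass
class ReflexAnalysis:
    """All reflex quantities of one session: cycle labels, per-muscle
    blEMG, per-(muscle, bin) traces, and the detected-response table."""

    condition: str
    labels: np.ndarray
    blemg: dict[tuple[str, str], BaselineProfile]
    traces: dict[tuple[str, str, int], BinTraces]
    responses: pd.DataFrame
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))


def analyze_session_reflexes(
    emg: EmgRecording,
    onsets: np.ndarray,
    cfg: AnalysisConfig | None = None,
    condition: str = "",
) -> ReflexAnalysis:
    """Run the full reflex chain (tagging, blEMG, binning, detection,
    classification, net values) on one session."""
    cfg = cfg or AnalysisConfig()
    onsets = np.asarray(onsets, dtype=float)
    durations = np.diff(onsets)
    labels = tag_cycles(onsets, emg.stim_times)
    ctrl = np.flatnonzero(labels == "C")

    bins = assign_bins(emg.stim_times, onsets, cfg.n_bins)
    valid = bins >= 0
    stim_t = emg.stim_times[valid]
    stim_b = bins[valid]
    cyc_idx = np.searchsorted(onsets, stim_t, side="right") - 1
    stim_u = (stim_t - onsets[cyc_idx]) / durations[cyc_idx]

    blemg: dict[tuple[str, str], BaselineProfile] = {}
    traces: dict[tuple[str, str, int], BinTraces] = {}
    rows = []
    for ch, (muscle, limb) in enumerate(emg.channels):
        x = emg.data[ch]
        blemg[(muscle, limb)] = build_blemg(
            x, emg.rate, onsets, labels, muscle, limb, cfg.n_bins, cfg.n_norm_points
        )
        relation = limb_relation(limb, emg.stim_limb)
        for b in range(cfg.n_bins):
            sel = stim_b == b
            if sel.sum() < cfg.min_stimuli:
                log.info("%s/%s bin %d: %d stimuli < %d, skipped", muscle, limb, b, sel.sum(), cfg.min_stimuli)
                continue
            tr = stim_triggered_traces(
                x,
                emg.rate,
                stim_t[sel],
                stim_u[sel],
                onsets[ctrl],
                durations[ctrl],
                cfg,
                muscle,
                limb,
                b,
            )
            traces[(muscle, limb, b)] = tr
            det = detect_response(tr, cfg)
            if det is None:
                continue
            klass, gap_flag = classify_response(det["onset_ms"], det["sign"], relation, cfg)
            net = net_reflex_value(
                tr.stim_mean, tr.ctrl_mean, emg.rate, (det["onset_ms"], det["offset_ms"])
            )
            rows.append(
                {
                    "muscle": muscle,
                    "limb": limb,
                    "relation": relation,
                    "bin": b,
                    "n_stim": int(sel.sum()),
                    "sign": det["sign"],
                    "onset_ms": det["onset_ms"],
                    "offset_ms": det["offset_ms"],
                    "latency_class": klass,
                    "family": FAMILY_OF_CLASS[klass],
                    "gap_flagged": gap_flag,
                    "net_value": net,
                }
            )
    columns = [
        "muscle", "limb", "relation", "bin", "n_stim", "sign", "onset_ms",
        "offset_ms", "latency_class", "family", "gap_flagged", "net_value",
    ]
    responses = pd.DataFrame(rows, columns=columns)
    return ReflexAnalysis(
        condition=condition,
        labels=labels,
        blemg=blemg,
        traces=traces,
        responses=responses,
        onsets=onsets,
    )


def phase_profiles(
    analysis: ReflexAnalysis,
    cfg: AnalysisConfig | None = None,
    window_ms: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """10-bin net-reflex profiles per (muscle, latency family).

    The integration window is either given explicitly or taken as the
    consensus (median) onset/offset of the family's detected responses;
    every bin with enough stimuli is then integrated over that identical
    window, so phases without a detectable deflection contribute their
    (near-zero) net value instead of a missing one.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    resp = analysis.responses
    keys = (
        resp.groupby(["muscle", "limb", "family"]).size().index
        if len(resp)
        else []
    )
    for muscle, limb, family in keys:
        sub = resp[(resp.muscle == muscle) & (resp.limb == limb) & (resp.family == family)]
        if window_ms is None:
            win = (float(sub.onset_ms.median()), float(sub.offset_ms.median()))
        else:
            win = window_ms
        for b in range(cfg.n_bins):
            tr = analysis.traces.get((muscle, limb, b))
            net = (
                net_reflex_value(tr.stim_mean, tr.ctrl_mean,
                                 analysis_rate(analysis, tr), win)
                if tr is not None
                else float("nan")
            )
            det = sub[sub.bin == b]
            rows.append(
                {
                    "condition": analysis.condition,
                    "muscle": muscle,
                    "limb": limb,
                    "relation": sub.relation.iloc[0],
                    "family": family,
                    "bin": b,
                    "net_value": net,
                    "detected": bool(len(det)),
                    "latency_class": det.latency_class.iloc[0] if len(det) else "",
                    "window_onset_ms": win[0],
                    "window_offset_ms": win[1],
                }
            )
    return pd.DataFrame(rows)


def analysis_rate(analysis: ReflexAnalysis, tr: BinTraces) -> float:
    return 1000.0 / (tr.time_ms[1] - tr.time_ms[0])
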