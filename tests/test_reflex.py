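"""Reflex quantification: cycle tagging, blEMG, detection, classification,
net values, normalization, modulation, activity windows."""

import numpy as np
import pytest

import reflexgait as rg
from reflexgait.config import AnalysisConfig
from reflexgait.reflex import (
    BaselineProfile,
    BinTraces,
    activity_windows,
    assign_stim_phase,
    build_blemg,
    classify_response,
    detect_response,
    modulation_index,
    net_reflex_value,
    normalize_responses,
    tag_cycles,
)
from reflexgait.synthetic import window_samples


class TestTagCycles:
    def test_post_stimulation_cycle_excluded(self):
        onsets = np.arange(0.0, 7.0)
        labels = tag_cycles(onsets, np.array([3.5]))
        assert list(labels) == ["C", "C", "C", "S", "X", "C"]

    def test_no_stimuli_all_control(self):
        assert list(tag_cycles(np.arange(4.0), np.empty(0))) == ["C", "C", "C"]

    def test_stimulus_at_onset_belongs_to_opening_cycle(self):
        labels = tag_cycles(np.array([0.0, 1.0, 2.0, 3.0]), np.array([1.0]))
        assert list(labels) == ["C", "S", "X"]


class TestAssignPhase:
    @pytest.mark.parametrize("frac, expected", [(0.55, 5), (0.0, 0), (0.999, 9)])
    def test_floor_with_clamp(self, frac, expected):
        assert assign_stim_phase(10.0 + frac, 10.0, 1.0) == expected

    def test_outside_cycle_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assign_stim_phase(2.5, 0.0, 1.0)


class TestBlemg:
    def test_constant_signal_constant_bins(self):
        x = np.full(10000, 3.0)
        onsets = np.array([1.0, 3.0, 5.0, 7.0])
        labels = np.array(["C", "C", "C"])
        prof = build_blemg(x, 1000.0, onsets, labels)
        assert np.allclose(prof.bin_means, 3.0)
        assert prof.n_control == 3

    def test_burst_confined_to_early_bins(self):
        rate, onsets = 1000.0, np.array([0.0, 1.0, 2.0, 3.0])
        x = np.zeros(3100)
        for o in onsets[:-1]:
            i = int(o * rate)
            x[i : i + 500] = 2.0  # active during bins 0-4 of every cycle
        prof = build_blemg(x, rate, onsets, np.array(["C", "C", "C"]))
        assert np.all(prof.bin_means[:5] > 1.5)
        assert np.all(prof.bin_means[5:] < 0.1)

    def test_no_control_cycles_is_an_error(self):
        with pytest.raises(ValueError, match="control"):
            build_blemg(np.zeros(100), 1000.0, np.array([0.0, 0.05]), np.array(["S"]))

    def test_matches_generator_envelope(self, noiseless_bundle, noiseless_analysis):
        """On a noise-free session the blEMG reproduces the injected burst
        envelope (its own activity window, peak, and resting tone)."""
        cfg = noiseless_bundle.config
        prof = noiseless_analysis.blemg[("SOL", "LH")]
        spec = next(m for m in cfg.muscles if m.name == "SOL" and m.limb == "LH")
        u = (np.arange(200) + 0.5) / 200
        a, b = spec.window
        analytic = cfg.tone + np.where(
            (u >= a) & (u <= b),
            spec.peak * (0.5 - 0.5 * np.cos(2 * np.pi * (u - a) / (b - a))),
            0.0,
        )
        analytic_bins = analytic.reshape(10, 20).mean(axis=1)
        assert np.allclose(prof.bin_means, analytic_bins, atol=0.02)


def make_traces(rate=2000.0, window_ms=80.0, bump_onset=None, bump_dur=8.0, amp=0.5, half=0.05):
    n = int(window_ms * rate / 1000.0) + 1
    t = np.arange(n) / rate * 1000.0
    ctrl = np.ones(n)
    stim = ctrl.copy()
    if bump_onset is not None:
        k0, k1 = window_samples(rate, bump_onset, bump_onset + bump_dur)
        stim[k0 : k1 + 1] += amp * (0.5 - 0.5 * np.cos(2 * np.pi * np.arange(k1 - k0 + 1) / (k1 - k0)))
    return BinTraces(
        muscle="X", limb="LH", bin=0, n_stim=10, n_control_segments=100,
        time_ms=t, stim_mean=stim, ctrl_mean=ctrl, stim_smooth=stim,
        ctrl_smooth=ctrl, halfwidth=np.full(n, half),
    )


class TestDetection:
    def test_no_deflection_no_response(self):
        assert detect_response(make_traces(), AnalysisConfig()) is None

    def test_known_bump_onset_recovered_within_2ms(self):
        tr = make_traces(bump_onset=12.0, bump_dur=8.0, amp=0.5)
        det = detect_response(tr, AnalysisConfig())
        assert det is not None and det["sign"] == 1
        assert det["onset_ms"] == pytest.approx(12.0, abs=2.0)
        assert det["offset_ms"] == pytest.approx(20.0, abs=2.0)

    def test_inhibition_detected_with_negative_sign(self):
        tr = make_traces(bump_onset=25.0, amp=-0.5)
        det = detect_response(tr, AnalysisConfig())
        assert det is not None and det["sign"] == -1

    def test_brief_excursion_ignored(self):
        tr = make_traces(bump_onset=12.0, bump_dur=2.0, amp=0.5)
        assert detect_response(tr, AnalysisConfig()) is None

    def test_injected_bumps_found_in_noiseless_session(self, noiseless_bundle, noiseless_analysis):
        resp = noiseless_analysis.responses
        for r in noiseless_bundle.ground_truth.responses:
            strong = [b for b, v in enumerate(r.profile) if abs(v) >= 0.5 * max(abs(x) for x in r.profile)]
            sub = resp[(resp.muscle == r.muscle) & (resp.limb == r.limb) & resp.bin.isin(strong)]
            assert len(sub), (r.muscle, r.limb)
            assert np.all(np.abs(sub.onset_ms - r.onset_ms) <= 2.0)


class TestClassification:
    @pytest.mark.parametrize(
        "onset, sign, relation, expected",
        [
            (10.0, 1, "homonymous", "P1"),
            (25.0, -1, "homonymous", "N2"),
            (15.0, 1, "crossed", "P1"),
            (12.0, -1, "homonymous", "N1"),
            (47.0, 1, "homonymous", "P3"),
            (26.0, 1, "diagonal", "P2"),
            (40.0, -1, "homolateral", "N3"),
        ],
    )
    def test_latency_windows(self, onset, sign, relation, expected):
        klass, flagged = classify_response(onset, sign, relation)
        assert klass == expected and not flagged

    @pytest.mark.parametrize("onset, expected", [(18.4, "P1"), (18.7, "P2"), (34.5, "P2"), (34.9, "P3")])
    def test_gap_onsets_assigned_to_nearer_window_flagged(self, onset, expected):
        klass, flagged = classify_response(onset, 1, "homonymous")
        assert klass == expected and flagged

    def test_artifact_latency_rejected(self):
        with pytest.raises(ValueError, match="artifact"):
            classify_response(5.0, 1, "homonymous")


class TestNetValue:
    def test_identical_traces_give_zero(self):
        tr = make_traces()
        assert net_reflex_value(tr.stim_mean, tr.ctrl_mean, 2000.0, (10.0, 20.0)) == 0.0

    @pytest.mark.parametrize("factor, expected", [(2.0, 1.0), (0.5, -0.5)])
    def test_ratio_formula(self, factor, expected):
        n = 161
        stim, ctrl = np.full(n, factor), np.ones(n)
        assert net_reflex_value(stim, ctrl, 2000.0, (10.0, 30.0)) == pytest.approx(expected)

    def test_scale_invariance_exact(self, noiseless_analysis):
        tr = next(iter(noiseless_analysis.traces.values()))
        v1 = net_reflex_value(tr.stim_mean, tr.ctrl_mean, 2000.0, (10.0, 25.0))
        v2 = net_reflex_value(2.0 * tr.stim_mean, 2.0 * tr.ctrl_mean, 2000.0, (10.0, 25.0))
        assert v1 == v2

    def test_vanishing_baseline_flagged(self):
        with pytest.warns(UserWarning, match="floor"):
            assert np.isnan(net_reflex_value(np.ones(200), np.zeros(200), 2000.0, (10.0, 20.0)))


class TestNormalizationAndIndex:
    def test_signed_max_maps_to_100(self):
        out = normalize_responses(np.array([90.0, -30.0, 45.0]))
        assert np.allclose(out, [100.0, -100.0 / 3.0, 50.0])

    def test_all_zero_stays_zero(self):
        assert np.allclose(normalize_responses(np.zeros(10)), 0.0)

    def test_abs_max_mode(self):
        out = normalize_responses(np.array([50.0, -100.0]), mode="abs_max")
        assert np.allclose(out, [50.0, -100.0])

    def test_index_exceeds_100_with_sign_change(self):
        bins = np.array([100.0, 20.0, -20.0, 10.0, 5.0, 0.0, 40.0, 60.0, 30.0, 15.0])
        assert modulation_index(bins) == pytest.approx(120.0)

    def test_index_zero_for_flat_profile(self):
        assert modulation_index(np.full(10, 55.0)) == 0.0

    def test_index_from_two_bins(self):
        assert modulation_index(np.array([100.0, 40.0] + [np.nan] * 8)) == pytest.approx(60.0)

    def test_index_undefined_below_two_bins(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(modulation_index(np.array([np.nan] * 9 + [50.0])))


class TestActivityWindows:
    def test_mid_activity_window_around_midpoint(self):
        bins = np.zeros(10)
        bins[2:8] = 1.0  # active over normalized 0.2-0.8
        prof = BaselineProfile("M", "LH", np.repeat(bins, 20), bins, 20)
        w = activity_windows(prof)
        assert w["active_bins"] == [2, 3, 4, 5, 6, 7]
        assert w["mid_activity"] == (pytest.approx(0.425), pytest.approx(0.575))

    def test_silent_channel_has_no_active_window(self):
        prof = BaselineProfile("M", "LH", np.zeros(200), np.zeros(10), 20)
        with pytest.warns(UserWarning, match="no activity"):
            w = activity_windows(prof)
        assert w["activity"] is None

    def test_generator_window_recovered_within_one_bin(self, noiseless_analysis, noiseless_bundle):
        spec = next(
            m for m in noiseless_bundle.config.muscles if m.name == "SOL" and m.limb == "LH"
        )
        w = activity_windows(noiseless_analysis.blemg[("SOL", "LH")])
        start, end = w["activity"]
        assert abs(start - spec.window[0]) <= 0.1 + 1e-9
        assert abs(end - spec.window[1]) <= 0.1 + 1e-9
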