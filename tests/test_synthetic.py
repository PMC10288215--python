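"""The synthetic session generator: determinism, realized targets,
stimulus scheduling, and the injected-response forward model."""

import numpy as np
import pytest

import reflexgait as rg
from reflexgait.config import NoiseSpec, SessionConfig, noiseless_config
from reflexgait.coordination import circ_mean_r, coupling_angles
from reflexgait.synthetic import (
    ResponseSpec,
    assign_bins,
    generate_emg,
    generate_gait_events,
    generate_session,
    generate_stim_times,
)


class TestConfigValidation:
    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SessionConfig(condition="tied_slow", left_speed=-0.4, right_speed=0.4)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError, match="20"):
            rg.condition_config("tied_slow", n_cycles=10)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            rg.condition_config("tied_slow", emg_sample_rate=500.0)

    def test_stance_fraction_must_stay_below_one(self):
        with pytest.raises(ValueError, match="stance fraction"):
            rg.condition_config("tied_slow", stance_fraction_model=(1.2, 0.0))

    def test_stim_gap_range_constrained(self):
        with pytest.raises(ValueError, match=r"\[2, 4\]"):
            rg.StimSpec(gap_cycles=(1, 4))

    def test_bad_response_onset_rejected(self):
        with pytest.raises(ValueError, match="outside the latency class windows"):
            ResponseSpec("SOL", "LH", 5.0, 8.0, (0,) * 10)


class TestDeterminism:
    def test_identical_config_and_seed_bit_identical(self):
        a = generate_session(rg.condition_config("split_slow", seed=5, n_cycles=25, emg_sample_rate=1000.0))
        b = generate_session(rg.condition_config("split_slow", seed=5, n_cycles=25, emg_sample_rate=1000.0))
        assert np.array_equal(a.emg.data, b.emg.data)
        assert np.array_equal(a.emg.stim_times, b.emg.stim_times)
        for limb in a.gait_events:
            ea, eb = a.gait_events[limb], b.gait_events[limb]
            assert np.array_equal(ea.contact_times, eb.contact_times)
            assert np.array_equal(ea.liftoff_x, eb.liftoff_x)

    def test_different_seed_differs(self):
        a = generate_session(rg.condition_config("tied_slow", seed=5, n_cycles=25, emg_sample_rate=1000.0))
        b = generate_session(rg.condition_config("tied_slow", seed=6, n_cycles=25, emg_sample_rate=1000.0))
        assert not np.array_equal(a.emg.stim_times, b.emg.stim_times)


class TestCouplingRealization:
    def test_infinite_concentration_realizes_targets_exactly(self):
        cfg = noiseless_config("tied_slow", seed=0, n_cycles=30)
        events = generate_gait_events(cfg)
        for pair, (mean, _) in cfg.phase_targets.items():
            angles = coupling_angles(events, pair, "phase")
            assert np.allclose(angles, mean, atol=1e-6), pair

    @pytest.mark.parametrize("condition, target", [("split_slow", 270.0), ("split_fast", 90.0)])
    def test_split_gap_targets_recovered(self, condition, target):
        cfg = rg.condition_config(condition, seed=2, n_cycles=100)
        events = generate_gait_events(cfg)
        for pair in ("forelimb", "hindlimb"):
            s = circ_mean_r(coupling_angles(events, pair, "gap"))
            d = abs((s.mean_direction - target + 180.0) % 360.0 - 180.0)
            assert d < 5.0, (condition, pair)

    def test_near_infinite_concentration_converges_within_2deg(self):
        cfg = rg.condition_config(
            "tied_slow",
            seed=1,
            n_cycles=200,
            phase_targets={k: (m, 5000.0) for k, (m, _) in rg.config.PHASE_TARGETS["tied_slow"].items()},
        )
        events = generate_gait_events(cfg)
        for pair, (mean, _) in cfg.phase_targets.items():
            s = circ_mean_r(coupling_angles(events, pair, "phase"))
            assert abs((s.mean_direction - mean + 180.0) % 360.0 - 180.0) < 2.0


class TestStimulusTrain:
    def test_count_bounded_by_gap_range(self):
        cfg = rg.condition_config("tied_slow", seed=4, n_cycles=120)
        events = generate_gait_events(cfg)
        stims = generate_stim_times(cfg, events)
        assert 30 <= len(stims) <= 60

    def test_fixed_seed_reproduces_train(self):
        cfg = rg.condition_config("tied_slow", seed=4, n_cycles=40)
        events = generate_gait_events(cfg)
        assert np.array_equal(generate_stim_times(cfg, events), generate_stim_times(cfg, events))

    def test_phase_bins_uniformly_populated(self):
        """~10,000 stimuli spread over the 10 bins at 10% +/- 1% each."""
        cfg = rg.condition_config("tied_slow", seed=8, n_cycles=30000)
        events = generate_gait_events(cfg)
        stims = generate_stim_times(cfg, events)
        assert len(stims) > 7000
        bins = assign_bins(stims, events[cfg.stim.limb].contact_times)
        frac = np.bincount(bins[bins >= 0], minlength=10) / (bins >= 0).sum()
        assert np.all(np.abs(frac - 0.10) < 0.01)

    def test_phase_coverage_at_protocol_scale(self):
        """With ~120 stimuli per session, every bin gets >= 4 stimuli in
        >= 95% of seeds."""
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = rg.condition_config("tied_slow", seed=seed, n_cycles=360)
            events = generate_gait_events(cfg)
            stims = generate_stim_times(cfg, events)
            bins = assign_bins(stims, events[cfg.stim.limb].contact_times)
            if np.bincount(bins[bins >= 0], minlength=10).min() >= 4:
                ok += 1
        assert ok / n_seeds >= 0.95


class TestEmgForwardModel:
    def test_null_injection_leaves_stimulated_cycles_unchanged(self):
        """With an all-zero amplitude profile the EMG is independent of the
        stimulus train."""
        cfg = rg.condition_config("tied_slow", seed=13, n_cycles=30, emg_sample_rate=1000.0)
        null = tuple(
            ResponseSpec(r.muscle, r.limb, r.onset_ms, r.duration_ms, (0.0,) * 10)
            for r in rg.synthetic.DEFAULT_RESPONSES
        )
        rng = np.random.default_rng(cfg.seed)
        events = generate_gait_events(cfg, rng)
        stims = generate_stim_times(cfg, events, rng)
        state = rng.bit_generator.state
        emg_null, _ = generate_emg(cfg, events, stims, null, rng)
        rng.bit_generator.state = state
        emg_none, _ = generate_emg(cfg, events, np.empty(0), null, rng)
        assert np.array_equal(emg_null.data, emg_none.data)

    def test_single_stimulus_alters_channel_only_in_response_window(self):
        """Noise off, one stimulus, short-latency onset 10 ms: the channel
        deviates from its envelope only within [10 ms, 10 ms + duration]."""
        cfg = noiseless_config("tied_slow", seed=0, n_cycles=20)
        resp = (ResponseSpec("SOL", "LH", 10.0, 8.0, (1.0,) * 10),)
        events = generate_gait_events(cfg)
        t_stim = np.array([events["LH"].contact_times[5] + 0.213])
        t_stim = np.round(t_stim * cfg.emg_sample_rate) / cfg.emg_sample_rate
        emg_with, truth = generate_emg(cfg, events, t_stim, resp)
        emg_without, _ = generate_emg(cfg, events, np.empty(0), resp)
        diff = np.abs(emg_with.channel("SOL", "LH") - emg_without.channel("SOL", "LH"))
        changed = np.flatnonzero(diff > 1e-12) / cfg.emg_sample_rate - t_stim[0]
        assert changed.size > 0
        assert changed.min() >= 10e-3 - 1e-9
        assert changed.max() <= 18e-3 + 1e-9
        assert truth.truncated_stims == ()

    def test_rectified_signal_nonnegative(self, noisy_bundle):
        assert noisy_bundle.emg.data.min() >= 0.0

    def test_stims_inside_recording(self, noisy_bundle):
        noisy_bundle.validate()
        assert noisy_bundle.emg.stim_times.max() < noisy_bundle.emg.duration
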