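"""Shared fixtures: synthetic sessions at the study conditions.

Session-scoped bundles are generated once; problem sizes (cycle counts and
a 2 kHz sample rate) are chosen so every phase bin is well populated while
the whole suite stays light.
"""

import numpy as np
import pytest

import reflexgait as rg
from reflexgait.config import AnalysisConfig, noiseless_config
from reflexgait.pipeline import reference_onsets
from reflexgait.reflex import analyze_session_reflexes


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Fully deterministic tied-slow session: all noise off, couplings
    pinned at their targets, 1.0 s cycles on the 2 kHz sample grid."""
    cfg = noiseless_config("tied_slow", seed=3, n_cycles=400, emg_sample_rate=2000.0)
    return rg.generate_session(cfg)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_bundle, analysis_config):
    return analyze_session_reflexes(
        noiseless_bundle.emg,
        reference_onsets(noiseless_bundle, analysis_config),
        analysis_config,
        "tied_slow",
    )


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-noise tied-slow session sized for >= 12 stimuli per phase
    bin (signal-to-noise of the strongest responses ~ 5 or more)."""
    cfg = rg.condition_config("tied_slow", seed=11, n_cycles=600, emg_sample_rate=2000.0)
    return rg.generate_session(cfg)


@pytest.fixture(scope="session")
def noisy_analysis(noisy_bundle, analysis_config):
    return analyze_session_reflexes(
        noisy_bundle.emg,
        reference_onsets(noisy_bundle, analysis_config),
        analysis_config,
        "tied_slow",
    )


@pytest.fixture()
def small_config():
    return rg.condition_config("tied_slow", seed=7, n_cycles=40, emg_sample_rate=1000.0)


FAMILY_OF_ONSET = {12.0: "short", 26.0: "mid", 47.0: "long"}


def recovered_profile(bundle, analysis, response, cfg, window_ms=None):
    """10-bin net-reflex profile for one injected response."""
    from reflexgait.reflex import phase_profiles

    prof = phase_profiles(analysis, cfg, window_ms=window_ms)
    fam = FAMILY_OF_ONSET[response.onset_ms]
    sub = prof[
        (prof.muscle == response.muscle)
        & (prof.limb == response.limb)
        & (prof.family == fam)
    ].sort_values("bin")
    return sub.net_value.to_numpy(), np.asarray(response.profile, dtype=float)
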