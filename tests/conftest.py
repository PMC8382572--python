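"""Shared fixtures: small simulated recordings reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import brainvitals as bv


@pytest.fixture(scope="session")
def default_profile() -> bv.ParticipantProfile:
    return bv.ParticipantProfile(id="p1")


@pytest.fixture(scope="session")
def truth(default_profile) -> dict[str, tuple[float, float]]:
    """(amplitude, latency) ground truth per component for the default profile."""
    return {k: (v.amplitude, v.latency) for k, v in default_profile.true_components.items()}


@pytest.fixture(scope="session")
def short_sequences():
    tones = bv.generate_tone_sequence(40, 0.2, isi=1.1, seed=2)
    words = bv.generate_word_pair_sequence(20, 0.5, seed=3, start=48.0)
    return tones, words


@pytest.fixture(scope="session")
def noiseless_recording(default_profile, short_sequences) -> bv.RawRecording:
    tones, words = short_sequences
    silent = bv.NoiseConfig(background_sd_uv=0.0, blink_rate_hz=0.0)
    return bv.synthesize_recording(default_profile, tones, words, silent, seed=4)


@pytest.fixture(scope="session")
def noiseless_measures(noiseless_recording) -> dict[str, float]:
    return bv.process_recording(noiseless_recording, participant_id="p1").as_dict()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
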