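"""Shared fixtures: small, seeded simulations reused across test modules."""

import numpy as np
import pytest

import svspread as sv


@pytest.fixture(scope="session")
def confined_sim():
    """Confined 40-event stimulation stack with mild noise, plus ground truth."""
    params = sv.FusionGroundTruth(
        D=0.30,
        event_times=sv.default_event_times(2.0),
        molecules_per_event=100,
        bouton_radius=1.15,
        background=100.0,
        noise_sd=2.0,
        psf_sigma=0.15,
        frame_interval=0.4,
        stim_start=2.0,
        stim_end=4.0,
        n_frames=30,
        image_shape=(48, 48),
        seed=11,
    )
    seq, traj = sv.simulate_fusion_sequence(params)
    return params, seq, traj


@pytest.fixture(scope="session")
def free_sim():
    """Unbounded 40-event stimulation stack (free diffusion), noiseless."""
    params = sv.FusionGroundTruth(
        D=0.30,
        event_times=sv.default_event_times(2.0),
        molecules_per_event=100,
        bouton_radius=None,
        background=50.0,
        noise_sd=0.0,
        psf_sigma=0.15,
        frame_interval=0.4,
        stim_start=2.0,
        stim_end=4.0,
        n_frames=14,
        image_shape=(64, 64),
        seed=7,
    )
    seq, traj = sv.simulate_fusion_sequence(params)
    return params, seq, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
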