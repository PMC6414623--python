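"""Shared fixtures: small, fast phantom configurations.

The reduced configs keep the physics of the full presets (same pixel
pitches per unit length, same cardiac model, same Doppler scale) but use
narrower/shallower frames so that a full simulate+process+quantify pass
takes well under a second.
"""

import numpy as np
import pytest

from srvp import phantom


def small_config(**overrides):
    """A compact single-channel phantom: 96 x 256 px, 3.2 s at 24 fps."""
    defaults = dict(
        n_ascans=256,
        depth_px=96,
        tissue_surface_px=12,
        bscan_length_mm=0.8,
        duration_s=3.2,
        vessel=phantom.VesselModel(
            center_z_px=48, a0_um=60.0, b0_um=60.0,
            m_lat=0.20, m_ax=0.375, doppler_angle_deg=60.0,
            intensity_mod=0.30,
        ),
        cardiac=phantom.CardiacModel(hrv_frac=0.0),
        snr_db=25.0,
        slo_size_px=128,
        seed=phantom.DEFAULT_SEED,
    )
    defaults.update(overrides)
    return phantom.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def s1_small():
    """Small subject-1-like phantom with its sequences and truth."""
    cfg = small_config()
    seqs, truths = phantom.simulate_complex_sequence(cfg)
    return cfg, seqs[0], truths[0]


@pytest.fixture(scope="session")
def s1_small_noisefree():
    cfg = small_config(snr_db=None)
    seqs, truths = phantom.simulate_complex_sequence(cfg)
    return cfg, seqs[0], truths[0]


@pytest.fixture
def uniform_time_grid():
    return np.arange(0.0, 3.2, 1.0 / 24.0)
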