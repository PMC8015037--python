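import numpy as np
import pytest

from cranioppg.synth import HemoDynamicsSpec, TrialProtocol, make_tissue, simulate_trial


def short_protocol(pre_s=6.0, stim_s=4.0, post_s=5.0, fps=50.0):
    """Compact protocol for unit tests (phases scaled down, cardiac content
    preserved)."""
    return TrialProtocol(pre_s=pre_s, stim_s=stim_s, post_s=post_s,
                         frame_rate_hz=fps)


@pytest.fixture(scope="session")
def tissue():
    return make_tissue(seed=1, height_px=96, width_px=96)


@pytest.fixture(scope="session")
def quiet_trial(tissue):
    """Noise-free, motion-free, stimulation-free trial: pure cardiac
    modulation."""
    hemo = HemoDynamicsSpec(noise_sd_counts=0.0, motion_amplitude_px=0.0,
                            stim_apc_gain=1.0, stim_volume_drop=0.0,
                            hr_variability=0.0, abp_dip_frac=0.0, hr_dip_frac=0.0)
    return simulate_trial(tissue, hemo, short_protocol(), seed=7)


@pytest.fixture(scope="session")
def stim_trial(tissue):
    """Noise-free, motion-free trial with the default stimulation response."""
    hemo = HemoDynamicsSpec(noise_sd_counts=0.0, motion_amplitude_px=0.0,
                            hr_variability=0.0)
    return simulate_trial(tissue, hemo, short_protocol(), seed=8)


def artery_tiles(tissue, apc_values, tile_px=3, label=1):
    """Boolean mask of APC tiles lying fully inside a vessel class."""
    nh, nw = apc_values.shape
    m = tissue.vessel_mask[:nh * tile_px, :nw * tile_px]
    m = m.reshape(nh, tile_px, nw, tile_px)
    return (m == label).all(axis=(1, 3))
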