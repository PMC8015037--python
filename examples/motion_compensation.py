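"""Segment-wise gradient motion compensation on a jittering recording.

Simulates a trial with default tissue motion (slow drift + fast tremor,
peak 1.5 px), estimates per-segment offsets against the first frame and
subtracts the motion-related intensity component, then shows how much
closer the APC map sits to the injected ground truth.
"""

import numpy as np

from cranioppg import motion, ppg
from cranioppg.synth import HemoDynamicsSpec, make_tissue, simulate_trial
from cranioppg.synth.kinetics import reduced_protocol

tissue = make_tissue(seed=1)
protocol = reduced_protocol()
hemo = HemoDynamicsSpec(stim_apc_gain=1.0, stim_volume_drop=0.0)  # motion 1.5 px, noise 1.0
rec = simulate_trial(tissue, hemo, protocol, seed=3)

grid = motion.make_grid(*rec.video.shape)
win = ppg.dc_window_frames(rec.rpeaks, protocol.frame_rate_hz)
field = motion.estimate_offsets(rec.video, grid, cardiac_window_frames=win)
stabilized = motion.compensate(rec.video, field, grid)

est = np.median(field.d.reshape(field.d.shape[0], -1, 2), axis=1)
err = np.abs(est - rec.ground_truth.motion_px).mean()
print(f"{grid.n_segments} segments of {grid.segment_px} px; "
      f"mean |offset error| vs injected motion: {err:.3f} px")

injected = {1: 100 * tissue.artery_pulsatility, 2: 100 * tissue.vein_pulsatility,
            0: 100 * tissue.background_pulsatility}

def apc_error(video):
    amap = ppg.apc_map(video, rec.rpeaks, 10.0)
    nh, nw = amap.values.shape
    m = tissue.vessel_mask[:nh * 3, :nw * 3].reshape(nh, 3, nw, 3)
    errs = [np.abs(amap.values[(m == c).all(axis=(1, 3))] - v)
            for c, v in injected.items()]
    return np.concatenate(errs).mean()

raw, comp = apc_error(rec.video), apc_error(stabilized)
print(f"APC error vs injected ground truth: raw {raw:.3f}%  compensated {comp:.3f}%")
print("Compensation removes the motion-related intensity component, pulling")
print("the recovered pulse amplitudes toward the injected values.")
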