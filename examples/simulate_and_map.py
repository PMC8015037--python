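"""Simulate one cranial-window trial and map the pulse amplitude (APC).

Builds a small synthetic cortex (arteries, veins, textured parenchyma),
renders a 60 s stimulation trial at 50 fps, and compares the APC map before
and during electrical stimulation.
"""

import numpy as np

from cranioppg import ppg
from cranioppg.synth import HemoDynamicsSpec, make_tissue, simulate_trial
from cranioppg.synth.kinetics import reduced_protocol

tissue = make_tissue(seed=1)  # 120 x 188 px, two arteries, two veins
protocol = reduced_protocol()  # 20 s pre / 15 s stim / 25 s post @ 50 fps
hemo = HemoDynamicsSpec(motion_amplitude_px=0.0)  # keep this example motion-free
rec = simulate_trial(tissue, hemo, protocol, seed=2)

pre_map = ppg.apc_map(rec.video, rec.rpeaks, at_time_s=10.0)
stim_map = ppg.apc_map(rec.video, rec.rpeaks, at_time_s=30.0)

nh, nw = pre_map.values.shape
classes = tissue.vessel_mask[:nh * 3, :nw * 3].reshape(nh, 3, nw, 3)
artery = (classes == 1).all(axis=(1, 3))
vein = (classes == 2).all(axis=(1, 3))

print(f"APC map: {nh} x {nw} tiles of 3 x 3 px")
print(f"pre-stimulation  artery median APC {np.nanmedian(pre_map.values[artery]):.2f}%  "
      f"vein {np.nanmedian(pre_map.values[vein]):.2f}%")
print(f"during stimulation artery median APC {np.nanmedian(stim_map.values[artery]):.2f}%")
print("Arteries pulsate far more than veins, and stimulation raises the")
print("pulse amplitude field-wide — the contrast the APC map visualizes.")
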