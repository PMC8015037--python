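"""Minimal synthetic electrogram: detectable R-peaks on a noisy baseline.

No attempt is made at full PQRST morphology; each beat is a narrow biphasic
QRS-like deflection placed at the ground-truth R-peak time.  Peaks land on
the 1 kHz sample grid, so the ECG/video clock offset is at most half a
sample (0.5 ms).
"""

from __future__ import annotations

import numpy as np

from ..datatypes import SampledTrace


def synthesize_ecg(rpeak_times_s: np.ndarray, duration_s: float,
                   rate_hz: float = 1000.0, rng: np.random.Generator | None = None,
                   r_amplitude_mv: float = 1.0, qrs_width_s: float = 0.008,
                   noise_sd_mv: float = 0.02) -> SampledTrace:
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    ecg = np.zeros(n)
    half = qrs_width_s / 2
    for rt in np.asarray(rpeak_times_s, dtype=float):
        lo = max(int((rt - 3 * half) * rate_hz), 0)
        hi = min(int((rt + 3 * half) * rate_hz) + 1, n)
        if lo >= hi:
            continue
        dt = t[lo:hi] - rt
        # R spike with small S undershoot (derivative-of-Gaussian flavour)
        ecg[lo:hi] += r_amplitude_mv * np.exp(-0.5 * (dt / half) ** 2)
        ecg[lo:hi] -= 0.25 * r_amplitude_mv * np.exp(-0.5 * ((dt - 2 * half) / half) ** 2)
    if noise_sd_mv > 0:
        ecg += noise_sd_mv * rng.standard_normal(n)
    return SampledTrace(values=ecg, rate_hz=rate_hz, name="ecg", units="mV")
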