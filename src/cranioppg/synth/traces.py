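"""Trace-level forward model: per-trial APC/OIS/ABP/HR time courses.

Group-level statistics operate on big-ROI trial traces, not on raw frames,
so whole experiments and replicate cohorts are simulated directly at the
trace level with the same hemodynamic kinetics as the video model.  The
OIS trace is expressed as 100 + OIS(%) so its pre-stimulation level is
~100% and pre-stimulation normalization is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datatypes import SampledTrace
from .kinetics import HemoDynamicsSpec, TrialProtocol, apc_gain_profile, dip_profile, volume_profile


@dataclass
class TraceSpec:
    """Scales and noise of the emitted traces.

    ``apc0_pct`` is the pre-stimulation APC of the representative big ROIs
    (percent); noise SDs are additive on each trace's native scale.
    """

    rate_hz: float = 10.0
    apc0_pct: float = 2.0
    abp0_mmhg: float = 72.0
    apc_noise_pct: float = 0.04
    ois_noise_pct: float = 0.5
    abp_noise_mmhg: float = 1.0
    hr_noise_bpm: float = 3.0


def simulate_trial_traces(hemo: HemoDynamicsSpec, protocol: TrialProtocol,
                          seed: int | np.random.Generator,
                          spec: TraceSpec | None = None) -> dict[str, SampledTrace]:
    """Simulate the four per-trial parameter traces of one trial."""
    spec = spec or TraceSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(protocol.total_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz

    apc = spec.apc0_pct * apc_gain_profile(t, protocol, hemo)
    apc = apc + spec.apc_noise_pct * rng.standard_normal(n)

    # 100 + OIS(%): volume_profile is the intensity factor V(t) <= 1
    ois = 100.0 + 100.0 * (1.0 - volume_profile(t, protocol, hemo))
    ois = ois + spec.ois_noise_pct * rng.standard_normal(n)

    dip = dip_profile(t, protocol, hemo)
    abp = spec.abp0_mmhg * (1.0 - hemo.abp_dip_frac * dip)
    abp = abp + spec.abp_noise_mmhg * rng.standard_normal(n)
    hr = hemo.heart_rate_bpm * (1.0 - hemo.hr_dip_frac * dip)
    hr = hr + spec.hr_noise_bpm * rng.standard_normal(n)

    rate = spec.rate_hz
    return {
        "APC": SampledTrace(values=apc, rate_hz=rate, name="apc", units="%"),
        "OIS": SampledTrace(values=ois, rate_hz=rate, name="ois", units="%"),
        "ABP": SampledTrace(values=abp, rate_hz=rate, name="abp", units="mmHg"),
        "HR": SampledTrace(values=hr, rate_hz=rate, name="hr", units="bpm"),
    }
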