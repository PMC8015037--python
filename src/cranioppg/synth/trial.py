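"""Video-level forward model of one stimulation trial.

Frame intensity at pixel p and time t is

    I(t, p) = clip( B(p) * V(t) * [1 + a(p) * g(t) * c(phi(t))] )

warped by the lateral tissue motion and corrupted by additive sensor noise,
where B is the baseline image, V the slow blood-volume intensity factor,
a the per-pixel pulsatility, g the stimulation gain profile, c the fixed
zero-mean cardiac pulse template and phi the cardiac phase defined by the
generated R-peaks.  ECG, ABP and HR traces are synchronized to the video
clock (offset <= 1 ms, set by the 1 kHz ECG grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..datatypes import RPeakSeries, SampledTrace, VideoRecording
from .ecg import synthesize_ecg
from .kinetics import (
    GroundTruth,
    HemoDynamicsSpec,
    TrialProtocol,
    apc_gain_profile,
    cardiac_phase,
    cardiac_template,
    dip_profile,
    generate_rpeak_times,
    volume_profile,
)
from .tissue import ARTERY, BACKGROUND, VEIN, TissueModel

log = logging.getLogger(__name__)

_CHUNK = 256  # frames per rendering chunk, bounds peak memory


@dataclass
class TrialRecording:
    video: VideoRecording
    ecg: SampledTrace
    rpeaks: RPeakSeries
    abp: SampledTrace
    hr: SampledTrace
    ground_truth: GroundTruth
    tissue: TissueModel
    protocol: TrialProtocol
    hemo: HemoDynamicsSpec


def _motion_trajectory(n_frames: int, frame_rate_hz: float, amplitude_px: float,
                       rng: np.random.Generator,
                       jitter_frac: float = 0.35) -> np.ndarray:
    """Global (dy, dx) offset per frame: slow drift (low-pass-filtered
    random walk) plus band-limited fast jitter (the respiratory/cardiogenic
    tissue tremor that intensity-based motion compensation targets).

    The trajectory is anchored at zero on the first frame (the
    motion-compensation reference) and scaled so the peak |offset|
    equals ``amplitude_px``.
    """
    if amplitude_px <= 0 or n_frames < 2:
        return np.zeros((n_frames, 2))
    walk = np.cumsum(rng.standard_normal((n_frames, 2)), axis=0)
    drift = ndimage.gaussian_filter1d(walk, sigma=0.5 * frame_rate_hz, axis=0)
    drift -= drift[0]
    drift *= (1.0 - jitter_frac) * amplitude_px / max(np.abs(drift).max(), 1e-12)
    jitter = ndimage.gaussian_filter1d(rng.standard_normal((n_frames, 2)),
                                       sigma=0.04 * frame_rate_hz, axis=0)
    jitter -= jitter[0]
    jitter *= jitter_frac * amplitude_px / max(np.abs(jitter).max(), 1e-12)
    return drift + jitter


def simulate_trial(tissue: TissueModel, hemo: HemoDynamicsSpec,
                   protocol: TrialProtocol, seed: int,
                   abp0_mmhg: float = 72.0) -> TrialRecording:
    """Render one trial: video + ECG + R-peaks + ABP/HR + ground truth."""
    rng = np.random.default_rng(seed)
    duration = protocol.total_s
    fps = protocol.frame_rate_hz
    n_frames = int(round(duration * fps))
    t = np.arange(n_frames) / fps

    # cardiac timing; snap peaks to the ECG sample grid (<= 0.5 ms offset)
    rpeaks = generate_rpeak_times(duration, hemo, protocol, rng)
    rpeaks = np.round(rpeaks * protocol.ecg_rate_hz) / protocol.ecg_rate_hz
    phase = cardiac_phase(t, rpeaks)

    g = apc_gain_profile(t, protocol, hemo).astype(np.float32)
    v = volume_profile(t, protocol, hemo).astype(np.float32)
    gc = (g * cardiac_template(phase).astype(np.float32))

    base = tissue.baseline_intensity.astype(np.float32)
    amap = tissue.pulsatility_map
    offsets = _motion_trajectory(n_frames, fps, hemo.motion_amplitude_px, rng)

    frames = np.empty((n_frames, tissue.height_px, tissue.width_px), dtype=np.float32)
    clipped = 0
    max_count = 1023.0
    for lo in range(0, n_frames, _CHUNK):
        hi = min(lo + _CHUNK, n_frames)
        chunk = 1.0 + gc[lo:hi, None, None] * amap[None]
        chunk *= v[lo:hi, None, None]
        chunk *= base[None]
        if hemo.motion_amplitude_px > 0:
            for j in range(lo, hi):
                chunk[j - lo] = ndimage.shift(chunk[j - lo], offsets[j],
                                              order=1, mode="nearest")
        if hemo.noise_sd_counts > 0:
            chunk += hemo.noise_sd_counts * rng.standard_normal(
                chunk.shape).astype(np.float32)
        clipped += int(np.count_nonzero((chunk < 0) | (chunk > max_count)))
        np.clip(chunk, 0, max_count, out=chunk)
        frames[lo:hi] = chunk
    if clipped:
        log.warning("%d pixel values clipped to the 10-bit range", clipped)

    video = VideoRecording(frames=frames, frame_rate_hz=fps,
                           pixel_pitch_um=tissue.pixel_pitch_um, bit_depth=10,
                           meta={"protocol": protocol.__dict__, "seed": seed})
    ecg = synthesize_ecg(rpeaks, duration, protocol.ecg_rate_hz, rng)

    abp_rate = 100.0
    t_abp = np.arange(int(round(duration * abp_rate))) / abp_rate
    abp_vals = abp0_mmhg * (1.0 - hemo.abp_dip_frac * dip_profile(t_abp, protocol, hemo))
    abp_vals = abp_vals + 0.5 * rng.standard_normal(t_abp.size)
    abp = SampledTrace(values=abp_vals, rate_hz=abp_rate, name="abp", units="mmHg")

    hr_rate = 10.0
    t_hr = np.arange(int(round(duration * hr_rate))) / hr_rate
    hr_vals = hemo.heart_rate_bpm * (1.0 - hemo.hr_dip_frac * dip_profile(t_hr, protocol, hemo))
    hr_vals = hr_vals + 1.0 * rng.standard_normal(t_hr.size)  # beat-timing jitter
    hr = SampledTrace(values=hr_vals, rate_hz=hr_rate, name="hr", units="bpm")

    gt = GroundTruth(
        t_s=t, apc_gain=g.astype(float), volume_factor=v.astype(float),
        injected_apc={
            BACKGROUND: tissue.background_pulsatility * g.astype(float),
            ARTERY: tissue.artery_pulsatility * g.astype(float),
            VEIN: tissue.vein_pulsatility * g.astype(float),
        },
        rpeak_times_s=rpeaks, motion_px=offsets, clipped_pixels=clipped,
    )
    return TrialRecording(video=video, ecg=ecg,
                          rpeaks=RPeakSeries(times_s=rpeaks, source="provided"),
                          abp=abp, hr=hr, ground_truth=gt,
                          tissue=tissue, protocol=protocol, hemo=hemo)
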