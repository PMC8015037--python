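"""Hemodynamic kinetics shared by the video and trace forward models.

The slow dynamics follow the qualitative shape of stimulation-evoked
meningeal responses: an increase that starts with stimulation onset, keeps
building during the 15 s stimulation, and relaxes mono-exponentially
afterwards so that the trace re-enters its pre-stimulation band 40-90 s
after stimulation onset.  Arterial pressure and heart rate show a faster
transient dip confined to the stimulation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialProtocol:
    """Timing of one stimulation trial.

    Defaults are the full protocol: 20 s pre-stimulation, 15 s electrical
    stimulation (biphasic 2 ms pulses, 10 Hz, 50 V — metadata only) and 85 s
    relaxation, recorded at 100 fps with 1 kHz ECG.
    """

    pre_s: float = 20.0
    stim_s: float = 15.0
    post_s: float = 85.0
    frame_rate_hz: float = 100.0
    ecg_rate_hz: float = 1000.0
    stim_pulse_ms: float = 2.0
    stim_freq_hz: float = 10.0
    stim_amp_v: float = 50.0

    def __post_init__(self) -> None:
        if min(self.pre_s, self.stim_s, self.post_s) <= 0:
            raise ValueError("all trial phases must have positive duration")
        if self.frame_rate_hz <= 0 or self.ecg_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def total_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def stim_onset_s(self) -> float:
        return self.pre_s

    @property
    def stim_end_s(self) -> float:
        return self.pre_s + self.stim_s


def reduced_protocol(frame_rate_hz: float = 50.0, post_s: float = 25.0) -> TrialProtocol:
    """Desk-scale protocol used throughout the tests: 20/15/post_s s at
    50 fps (60 s total by default)."""
    return TrialProtocol(pre_s=20.0, stim_s=15.0, post_s=post_s,
                         frame_rate_hz=frame_rate_hz)


@dataclass
class HemoDynamicsSpec:
    """Parameters of the hemodynamic forward model.

    ``stim_apc_gain`` multiplies the pulsatile amplitude at the peak of the
    stimulation response (>= 1); ``stim_volume_drop`` is the fractional
    reflected-intensity decrease at the response peak (green light is
    absorbed by blood, so a blood-volume increase darkens the image and
    drives a positive OIS).  ``relax_tau_s`` sets the mono-exponential
    post-stimulation relaxation.
    """

    heart_rate_bpm: float = 413.0
    hr_variability: float = 0.03  # fractional R-R jitter
    stim_apc_gain: float = 1.5
    stim_volume_drop: float = 0.10
    apc_onset_tau_s: float = 4.0
    vol_onset_tau_s: float = 8.0
    relax_tau_s: float = 12.0
    abp_dip_frac: float = 0.10
    hr_dip_frac: float = 0.07
    dip_tau_s: float = 3.0
    motion_amplitude_px: float = 1.5
    noise_sd_counts: float = 1.0

    def __post_init__(self) -> None:
        if self.stim_apc_gain < 1:
            raise ValueError("stim_apc_gain must be >= 1")
        if not 0 <= self.stim_volume_drop < 1:
            raise ValueError("stim_volume_drop must be in [0, 1)")
        if self.relax_tau_s <= 0:
            raise ValueError("relax_tau_s must be positive")
        for name in ("heart_rate_bpm", "hr_variability", "abp_dip_frac",
                     "hr_dip_frac", "motion_amplitude_px", "noise_sd_counts"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _slow_response(t: np.ndarray, protocol: TrialProtocol,
                   onset_tau_s: float, relax_tau_s: float) -> np.ndarray:
    """Normalized slow response r(t) in [0, 1]: exponential rise during
    stimulation, exponential relaxation afterwards; 0 before onset."""
    t = np.asarray(t, dtype=float)
    t_on, t_off = protocol.stim_onset_s, protocol.stim_end_s
    r = np.zeros_like(t)
    during = (t >= t_on) & (t < t_off)
    r[during] = 1.0 - np.exp(-(t[during] - t_on) / onset_tau_s)
    r_peak = 1.0 - np.exp(-(t_off - t_on) / onset_tau_s)
    after = t >= t_off
    r[after] = r_peak * np.exp(-(t[after] - t_off) / relax_tau_s)
    return r


def apc_gain_profile(t: np.ndarray, protocol: TrialProtocol, hemo: HemoDynamicsSpec) -> np.ndarray:
    """Multiplicative pulsatility gain g(t) >= 1; injected APC = a * g(t)."""
    r = _slow_response(t, protocol, hemo.apc_onset_tau_s, hemo.relax_tau_s)
    return 1.0 + (hemo.stim_apc_gain - 1.0) * r


def volume_profile(t: np.ndarray, protocol: TrialProtocol, hemo: HemoDynamicsSpec) -> np.ndarray:
    """Slow intensity factor V(t) <= 1: reflected intensity drops by
    ``stim_volume_drop`` at the response peak."""
    r = _slow_response(t, protocol, hemo.vol_onset_tau_s, hemo.relax_tau_s)
    return 1.0 - hemo.stim_volume_drop * r


def dip_profile(t: np.ndarray, protocol: TrialProtocol, hemo: HemoDynamicsSpec) -> np.ndarray:
    """Fast transient in [0, 1] for the ABP/HR dips: rises and recovers with
    ``dip_tau_s``, essentially confined to the stimulation epoch."""
    return _slow_response(t, protocol, hemo.dip_tau_s, hemo.dip_tau_s)


def cardiac_template(phase: np.ndarray) -> np.ndarray:
    """Fixed arterial pulse shape c(phi) over one cardiac cycle.

    Asymmetric (fast systolic rise over 30% of the cycle, slow decay),
    C1-smooth, zero-mean over the cycle and normalized to max - min = 1, so
    the injected fractional pulse amplitude is exactly a(p) * g(t).
    """
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    rise = phi < 0.3
    b = np.empty_like(phi)
    b[rise] = 0.5 * (1.0 - np.cos(np.pi * phi[rise] / 0.3))
    b[~rise] = 0.5 * (1.0 + np.cos(np.pi * (phi[~rise] - 0.3) / 0.7))
    return b - 0.5  # analytic cycle mean of b is 0.5


def generate_rpeak_times(duration_s: float, hemo: HemoDynamicsSpec,
                         protocol: TrialProtocol, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing R-peak times over [0, duration_s).

    The instantaneous rate follows the nominal heart rate with the transient
    stimulation dip; each R-R interval gets multiplicative Gaussian jitter
    of fractional SD ``hr_variability``.
    """
    times = []
    t = 0.0
    base_rr = 60.0 / hemo.heart_rate_bpm
    while t < duration_s:
        times.append(t)
        dip = dip_profile(np.array([t]), protocol, hemo)[0]
        rr = base_rr / max(1.0 - hemo.hr_dip_frac * dip, 1e-3)
        if hemo.hr_variability > 0:
            rr *= max(1.0 + hemo.hr_variability * rng.standard_normal(), 0.2)
        t += rr
    return np.asarray(times)


def cardiac_phase(t: np.ndarray, rpeaks: np.ndarray) -> np.ndarray:
    """Fractional cardiac phase of each time point given R-peak times.

    Points before the first or after the last peak extrapolate with the
    nearest R-R interval.
    """
    t = np.asarray(t, dtype=float)
    if rpeaks.size < 2:
        raise ValueError("need at least two R-peaks to define a phase")
    idx = np.clip(np.searchsorted(rpeaks, t, side="right") - 1, 0, rpeaks.size - 2)
    rr = rpeaks[idx + 1] - rpeaks[idx]
    return (t - rpeaks[idx]) / rr


@dataclass
class GroundTruth:
    """Injected signals recorded by the generator for verification."""

    t_s: np.ndarray
    apc_gain: np.ndarray  # g(t) at frame times
    volume_factor: np.ndarray  # V(t) at frame times
    injected_apc: dict = field(default_factory=dict)  # class -> a * g(t)
    rpeak_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    motion_px: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    clipped_pixels: int = 0
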