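"""ECG-gated photoplethysmography: AC/DC waveforms, 10-cycle mean pulses
and APC (amplitude of the pulsatile component) mapping.

Per small 3x3-px ROI the raw signal is the frame-by-frame mean pixel value.
Its slowly varying (DC) component is a centered moving average whose window
equals the median R-R interval (an odd number of frames), which nulls the
cardiac component in DC by construction; AC is the residual, and the
waveform of interest is the AC/DC ratio.  Heartbeat boundaries come from
ECG R-peaks; each R-R segment is resampled to a fixed number of phase
points and 10 consecutive cycles are averaged into a mean pulse.  APC is
(max - min) of the mean pulse, in percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .datatypes import APCMap, MeanPulse, PPGWaveform, RPeakSeries, SampledTrace, VideoRecording

DEFAULT_PHASE_POINTS = 50
DEFAULT_N_CYCLES = 10


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def detect_rpeaks(ecg: SampledTrace, refractory_s: float = 0.1,
                  band_hz: tuple[float, float] = (5.0, 35.0),
                  min_height_frac: float = 0.2) -> RPeakSeries:
    """Detect R-peaks: band-pass, squared derivative, adaptive threshold.

    The refractory period defaults to 100 ms — comfortably above the QRS
    width yet below the ~145 ms R-R interval of a rat heart at ~413 bpm.
    R-R gaps larger than 1.8x the median are recorded in ``gap_indices``
    (likely missed beats).
    """
    fs = ecg.rate_hz
    if fs < 250:
        raise ValueError("ECG sample rate must be at least 250 Hz")
    x = ecg.values - np.mean(ecg.values)
    if np.ptp(x) < 1e-12:
        return RPeakSeries(times_s=np.array([]), source="detected")
    sos = signal.butter(3, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    env = uniform_filter1d(np.gradient(filt) ** 2, max(int(0.02 * fs), 1))
    height = min_height_frac * np.percentile(env, 99)
    idx, _ = signal.find_peaks(env, height=height,
                               distance=max(int(refractory_s * fs), 1))
    # refine each candidate to the raw-ECG maximum within +-15 ms
    half = max(int(0.015 * fs), 1)
    refined = []
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    times = ecg.t0 + refined / fs
    rr = np.diff(times)
    gaps = np.flatnonzero(rr > 1.8 * np.median(rr)) if rr.size else np.array([], dtype=int)
    return RPeakSeries(times_s=times, source="detected", gap_indices=gaps)


# --------------------------------------------------------------------------
# DC/AC separation
# --------------------------------------------------------------------------

def dc_window_frames(rpeaks: RPeakSeries, frame_rate_hz: float) -> int:
    """Moving-average window (odd frame count) equal to the median R-R."""
    rr = rpeaks.rr_intervals_s
    if rr.size == 0:
        raise ValueError("need at least two R-peaks to set the DC window")
    w = int(round(float(np.median(rr)) * frame_rate_hz))
    w = max(w, 3)
    return w if w % 2 == 1 else w + 1


def dc_filter(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 (reflected edges)."""
    return uniform_filter1d(np.asarray(values, dtype=np.float32), window,
                            axis=0, mode="reflect")


def dc_filter_video(video: VideoRecording, rpeaks: RPeakSeries) -> VideoRecording:
    """Cardiac-free (DC) version of the whole stack; input to OIS."""
    w = dc_window_frames(rpeaks, video.frame_rate_hz)
    return video.copy_with(dc_filter(video.frames, w))


def tile_series(video: VideoRecording, tile_px: int = 3) -> np.ndarray:
    """Mean pixel value of every non-overlapping tile_px x tile_px ROI,
    anchored at (0, 0); residual rows/cols are dropped.  Shape (T, nh, nw)."""
    t, h, w = video.frames.shape
    nh, nw = h // tile_px, w // tile_px
    if nh == 0 or nw == 0:
        raise ValueError("frame smaller than one ROI tile")
    crop = video.frames[:, :nh * tile_px, :nw * tile_px].astype(np.float32)
    return crop.reshape(t, nh, tile_px, nw, tile_px).mean(axis=(2, 4))


def extract_waveform(frames_mc: VideoRecording, roi_origin: tuple[int, int],
                     rpeaks: RPeakSeries | None = None,
                     dc_window_s: float | None = None,
                     roi_px: int = 3) -> PPGWaveform:
    """AC/DC waveform of one small ROI of the (motion-compensated) stack.

    The DC window is the median R-R interval when ``rpeaks`` is given,
    otherwise ``dc_window_s`` must be provided.
    """
    r0, c0 = roi_origin
    h, w = frames_mc.shape
    if not (0 <= r0 <= h - roi_px and 0 <= c0 <= w - roi_px):
        raise ValueError("ROI not fully inside the frame")
    raw = frames_mc.frames[:, r0:r0 + roi_px, c0:c0 + roi_px].mean(axis=(1, 2))
    if rpeaks is not None:
        win = dc_window_frames(rpeaks, frames_mc.frame_rate_hz)
    elif dc_window_s is not None:
        win = max(int(round(dc_window_s * frames_mc.frame_rate_hz)) | 1, 3)
    else:
        raise ValueError("either rpeaks or dc_window_s is required")
    dc = dc_filter(raw, win).astype(float)
    valid = bool(np.all(dc > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ac_over_dc = np.where(dc > 0, (raw - dc) / dc, np.nan)
    return PPGWaveform(roi_origin=(r0, c0), t_s=frames_mc.times_s,
                       ac_over_dc=ac_over_dc, dc=dc, valid=valid)


# --------------------------------------------------------------------------
# Cardiac-cycle resampling and mean pulses
# --------------------------------------------------------------------------

def _resample_cycles(values: np.ndarray, t0: float, rate_hz: float,
                     rpeaks: np.ndarray, phase_points: int) -> np.ndarray:
    """Resample every R-R segment of a regularly sampled signal to
    ``phase_points`` by linear interpolation.

    ``values`` has shape (T, ...); the result has shape
    (n_cycles, phase_points, ...).
    """
    n_cycles = rpeaks.size - 1
    if n_cycles < 1:
        raise ValueError("need at least one complete R-R interval")
    phases = np.arange(phase_points) / phase_points
    starts = rpeaks[:-1, None]
    rr = np.diff(rpeaks)[:, None]
    t_sample = starts + phases[None, :] * rr  # (n_cycles, P)
    pos = (t_sample - t0) * rate_hz
    pos = np.clip(pos, 0, values.shape[0] - 1 - 1e-9)
    i0 = pos.astype(int)
    w = (pos - i0).astype(np.float32)
    flat = values.reshape(values.shape[0], -1)
    out = (1 - w)[..., None] * flat[i0] + w[..., None] * flat[i0 + 1]
    return out.reshape((n_cycles, phase_points) + values.shape[1:])


def mean_pulse(wave: PPGWaveform, rpeaks: RPeakSeries, start_cycle: int = 0,
               n_cycles: int = DEFAULT_N_CYCLES,
               phase_points: int = DEFAULT_PHASE_POINTS) -> MeanPulse:
    """Ensemble average of ``n_cycles`` consecutive cardiac cycles."""
    total = rpeaks.n_cycles()
    if start_cycle < 0 or total - start_cycle < n_cycles:
        raise ValueError(
            f"need {n_cycles} complete cycles from cycle {start_cycle}, "
            f"but only {max(total - start_cycle, 0)} are available")
    rate = 1.0 / float(np.median(np.diff(wave.t_s)))
    seg = rpeaks.times_s[start_cycle:start_cycle + n_cycles + 1]
    cyc = _resample_cycles(wave.ac_over_dc.astype(np.float32), wave.t_s[0],
                           rate, seg, phase_points)
    center = 0.5 * (seg[0] + seg[-1])
    return MeanPulse(phase=np.arange(phase_points) / phase_points,
                     values=cyc.mean(axis=0), n_cycles=n_cycles,
                     window_center_s=float(center))


def apc(pulse: MeanPulse) -> float:
    """APC (%): max - min of the mean PPG pulse, times 100."""
    return float((np.max(pulse.values) - np.min(pulse.values)) * 100.0)


# --------------------------------------------------------------------------
# APC maps and time courses
# --------------------------------------------------------------------------

def _tile_ac_dc(video: VideoRecording, rpeaks: RPeakSeries,
                tile_px: int) -> tuple[np.ndarray, np.ndarray]:
    tiles = tile_series(video, tile_px)
    win = dc_window_frames(rpeaks, video.frame_rate_hz)
    dc = dc_filter(tiles, win)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac_over_dc = np.where(dc > 0, (tiles - dc) / dc, np.nan)
    return ac_over_dc, dc


def _window_centers(rpeaks: np.ndarray, n_cycles: int) -> np.ndarray:
    return 0.5 * (rpeaks[:-n_cycles] + rpeaks[n_cycles:])


def apc_map(frames_mc: VideoRecording, rpeaks: RPeakSeries, at_time_s: float,
            tile_px: int = 3, n_cycles: int = DEFAULT_N_CYCLES,
            phase_points: int = DEFAULT_PHASE_POINTS) -> APCMap:
    """APC of every 3x3 tile, from the 10-cycle window centered nearest
    ``at_time_s``.  Tiles whose DC is non-positive anywhere are masked."""
    if rpeaks.n_cycles() < n_cycles:
        raise ValueError(f"need at least {n_cycles} cardiac cycles")
    ac_over_dc, dc = _tile_ac_dc(frames_mc, rpeaks, tile_px)
    centers = _window_centers(rpeaks.times_s, n_cycles)
    k = int(np.argmin(np.abs(centers - at_time_s)))
    seg = rpeaks.times_s[k:k + n_cycles + 1]
    bad = ~np.isfinite(ac_over_dc).all(axis=0)
    cyc = _resample_cycles(np.nan_to_num(ac_over_dc), frames_mc.t0,
                           frames_mc.frame_rate_hz, seg, phase_points)
    pulse = cyc.mean(axis=0)  # (P, nh, nw)
    values = (pulse.max(axis=0) - pulse.min(axis=0)) * 100.0
    mask = ~bad
    values[bad] = np.nan
    return APCMap(values=values, mask=mask, timestamp_s=float(centers[k]),
                  tile_px=tile_px)


def apc_timecourse(frames_mc: VideoRecording, rpeaks: RPeakSeries,
                   rois: list[tuple[int, int]], roi_px: int = 27,
                   tile_px: int = 3, n_cycles: int = DEFAULT_N_CYCLES,
                   phase_points: int = DEFAULT_PHASE_POINTS,
                   step_cycles: int = 1) -> pd.DataFrame:
    """APC time series of big ROIs: per-tile APC averaged over the ROI,
    computed with a sliding window of ``n_cycles`` cardiac cycles stepping
    by ``step_cycles``; timestamps are window centers.

    Returns a tidy frame (time_s, roi_id, apc_percent).
    """
    h, w = frames_mc.shape
    total = rpeaks.n_cycles()
    if total < n_cycles:
        raise ValueError(f"need at least {n_cycles} cardiac cycles")
    rows = []
    for roi_id, (r0, c0) in enumerate(rois):
        if not (0 <= r0 <= h - roi_px and 0 <= c0 <= w - roi_px):
            raise ValueError(f"ROI {roi_id} not fully inside the frame")
        sub = frames_mc.copy_with(frames_mc.frames[:, r0:r0 + roi_px, c0:c0 + roi_px])
        ac_over_dc, _ = _tile_ac_dc(sub, rpeaks, tile_px)
        cyc = _resample_cycles(np.nan_to_num(ac_over_dc), frames_mc.t0,
                               frames_mc.frame_rate_hz, rpeaks.times_s,
                               phase_points)  # (C, P, nh, nw)
        csum = np.concatenate([np.zeros((1,) + cyc.shape[1:], dtype=cyc.dtype),
                               np.cumsum(cyc, axis=0)])
        starts = np.arange(0, total - n_cycles + 1, step_cycles)
        centers = _window_centers(rpeaks.times_s, n_cycles)[starts]
        pulses = (csum[starts + n_cycles] - csum[starts]) / n_cycles
        apc_vals = (pulses.max(axis=1) - pulses.min(axis=1)) * 100.0
        apc_roi = apc_vals.reshape(apc_vals.shape[0], -1).mean(axis=1)
        rows.append(pd.DataFrame({"time_s": centers, "roi_id": roi_id,
                                  "apc_percent": apc_roi}))
    return pd.concat(rows, ignore_index=True)
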