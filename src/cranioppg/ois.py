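"""Optical intrinsic signals (OIS) and the stimulation-contact quality gate.

OIS_i(x, y) = (I_0 - I_i) / I_0 * 100%, with I_0 the first frame of the
trial's pre-stimulation phase.  Under green illumination OIS increases with
cerebral blood volume.  OIS is computed on the DC-filtered (cardiac-free),
motion-compensated sequence — heartbeat modulation of OIS is treated as
noise; raw-frame OIS is available behind a flag.

The quality gate requires the big-ROI mean OIS to rise by at least 7%
during the stimulation phase; a smaller rise indicates a poor electrode
contact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import OISMap, QCResult, RPeakSeries, VideoRecording
from .ppg import dc_filter_video
from .synth.kinetics import TrialProtocol

I0_EPSILON_COUNTS = 1.0  # pixels with I0 below this are masked
DEFAULT_QC_THRESHOLD_PCT = 7.0


def ois_frame(frames_mc_dc: VideoRecording, i: int, reference: int = 0,
              eps: float = I0_EPSILON_COUNTS) -> OISMap:
    """Per-pixel OIS (%) of frame ``i`` relative to the reference frame."""
    if not 0 <= i < frames_mc_dc.n_frames:
        raise ValueError("frame index out of range")
    i0 = frames_mc_dc.frames[reference].astype(np.float64)
    ii = frames_mc_dc.frames[i].astype(np.float64)
    mask = i0 > eps
    values = np.full(i0.shape, np.nan)
    values[mask] = (i0[mask] - ii[mask]) / i0[mask] * 100.0
    return OISMap(values=values, mask=mask, frame_index=i,
                  time_s=float(frames_mc_dc.times_s[i]), reference_index=reference)


def ois_timecourse(frames_mc: VideoRecording, rois: list[tuple[int, int]],
                   roi_px: int = 27, rpeaks: RPeakSeries | None = None,
                   protocol: TrialProtocol | None = None,
                   raw: bool = False, eps: float = I0_EPSILON_COUNTS) -> pd.DataFrame:
    """Mean OIS over each big ROI per frame.

    ``rpeaks`` sets the cardiac-rejection DC window; pass ``raw=True`` to
    skip the DC filtering.  Returns (time_s, roi_id, ois_percent[, phase]).
    """
    video = frames_mc if raw or rpeaks is None else dc_filter_video(frames_mc, rpeaks)
    h, w = video.shape
    t = video.times_s
    out = []
    for roi_id, (r0, c0) in enumerate(rois):
        if not (0 <= r0 <= h - roi_px and 0 <= c0 <= w - roi_px):
            raise ValueError(f"ROI {roi_id} outside the frame")
        block = video.frames[:, r0:r0 + roi_px, c0:c0 + roi_px].astype(np.float64)
        i0 = block[0]
        valid = i0 > eps
        if not valid.any():
            raise ValueError(f"ROI {roi_id} has no usable reference pixels")
        ois = ((i0[None] - block) / i0[None])[:, valid].mean(axis=1) * 100.0
        df = pd.DataFrame({"time_s": t, "roi_id": roi_id, "ois_percent": ois})
        out.append(df)
    result = pd.concat(out, ignore_index=True)
    if protocol is not None:
        result["phase"] = np.select(
            [result["time_s"] < protocol.stim_onset_s,
             result["time_s"] < protocol.stim_end_s],
            ["pre", "stim"], default="post")
    return result


def qc_gate(ois_series: pd.DataFrame, protocol: TrialProtocol,
            threshold_pct: float = DEFAULT_QC_THRESHOLD_PCT,
            trial_id: str = "") -> QCResult:
    """Contact quality: peak big-ROI mean OIS during stimulation minus the
    pre-stimulation mean must reach the threshold (default 7%)."""
    mean_series = (ois_series.groupby("time_s", sort=True)["ois_percent"]
                   .mean().reset_index())
    t = mean_series["time_s"].to_numpy()
    v = mean_series["ois_percent"].to_numpy()
    pre = v[t < protocol.stim_onset_s]
    stim = v[(t >= protocol.stim_onset_s) & (t < protocol.stim_end_s)]
    if pre.size == 0:
        raise ValueError("series does not cover the pre-stimulation phase")
    if stim.size == 0:
        raise ValueError("series does not cover the stimulation phase")
    increase = float(stim.max() - pre.mean())
    return QCResult(trial_id=trial_id, ois_increase_percent=increase,
                    threshold_percent=threshold_pct)
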