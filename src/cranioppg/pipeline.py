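"""End-to-end analysis chains tying the modules together.

Two entry points:

* :func:`analyze_trial_video` — the full video route for a single trial:
  motion compensation, R-peak gating, APC map at the 10th second of
  stimulation, big-ROI selection, APC/OIS time courses, QC gate,
  normalization and integral metrics;
* :func:`cohort_integrals` / :func:`group_report` — the experiment route:
  per-trial traces to baseline-normalized integral tables to the
  nonparametric group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import motion, ois, ppg, response, stats
from .datatypes import BigROISelection, NormalizedTrace, QCResult, RPeakSeries, TrialResponse
from .synth.experiment import ExperimentDataset
from .synth.kinetics import TrialProtocol
from .synth.trial import TrialRecording


@dataclass
class TrialAnalysis:
    rpeaks: RPeakSeries
    rois: BigROISelection
    apc_series: pd.DataFrame
    ois_series: pd.DataFrame
    qc: QCResult
    normalized: dict[str, NormalizedTrace]
    responses: list[TrialResponse]


def analyze_trial_video(rec: TrialRecording, compensate_motion: bool = True,
                        detect_rpeaks: bool = False,
                        qc_threshold_pct: float = ois.DEFAULT_QC_THRESHOLD_PCT,
                        trial_id: str = "trial") -> TrialAnalysis:
    """Run the full single-trial video analysis chain.

    By default the recorded R-peak series is used (external R-peaks take
    precedence); set ``detect_rpeaks=True`` to run the ECG detector instead.
    """
    video = rec.video
    rpeaks = ppg.detect_rpeaks(rec.ecg) if detect_rpeaks else rec.rpeaks
    if compensate_motion:
        grid = motion.make_grid(*video.shape)
        win = ppg.dc_window_frames(rpeaks, video.frame_rate_hz)
        field = motion.estimate_offsets(video, grid, cardiac_window_frames=win)
        video = motion.compensate(video, field, grid)

    protocol = rec.protocol
    stim_map_time = protocol.stim_onset_s + 10.0  # 10th s of stimulation
    amap = ppg.apc_map(video, rpeaks, at_time_s=stim_map_time)
    rois = response.select_big_rois(amap, rec.tissue.electrode_xy)
    rep_origins = [rois.origins[i] for i in rois.representative]

    apc_series = ppg.apc_timecourse(video, rpeaks, rep_origins, roi_px=rois.roi_px)
    ois_series = ois.ois_timecourse(video, rep_origins, roi_px=rois.roi_px,
                                    rpeaks=rpeaks, protocol=protocol)
    qc = ois.qc_gate(ois_series, protocol, qc_threshold_pct, trial_id=trial_id)

    apc_mean = apc_series.groupby("time_s")["apc_percent"].mean()
    ois_mean = ois_series.groupby("time_s")["ois_percent"].mean()
    normalized = {
        "APC": response.normalize_trace(apc_mean.index.to_numpy(),
                                        apc_mean.to_numpy(), protocol, "APC"),
        # 100 + OIS so the pre-stimulation level is ~100%
        "OIS": response.normalize_trace(ois_mean.index.to_numpy(),
                                        100.0 + ois_mean.to_numpy(), protocol, "OIS"),
        "ABP": response.normalize_trace(rec.abp.times_s, rec.abp.values, protocol, "ABP"),
        "HR": response.normalize_trace(rec.hr.times_s, rec.hr.values, protocol, "HR"),
    }
    responses = response.trial_response(normalized, protocol, trial_id=trial_id, qc=qc)
    return TrialAnalysis(rpeaks=rpeaks, rois=rois, apc_series=apc_series,
                         ois_series=ois_series, qc=qc, normalized=normalized,
                         responses=responses)


def trial_trace_metrics(traces: dict, protocol: TrialProtocol,
                        parameters: tuple[str, ...] = ("APC", "OIS", "ABP", "HR"),
                        ) -> dict[str, dict]:
    """Normalize one trial's traces and compute both integrals per parameter."""
    out = {}
    for p in parameters:
        tr = traces[p]
        nt = response.normalize_trace(tr.times_s, tr.values, protocol, p)
        fixed = response.integral_stim(nt, protocol)
        adaptive, end_s, truncated = response.integral_adaptive(nt, protocol)
        out[p] = {"normalized": nt, "integral_stim": fixed,
                  "integral_adaptive": adaptive, "integration_end_s": end_s,
                  "truncated": truncated}
    return out


def cohort_integrals(dataset: ExperimentDataset,
                     parameters: tuple[str, ...] = ("APC", "OIS", "ABP", "HR"),
                     ) -> pd.DataFrame:
    """Per-trial integral table of a simulated experiment, baseline-normalized
    per animal and parameter.

    Group comparisons use the fixed 20-35 s stimulation integral; the
    adaptive integral and its end time are carried alongside.
    """
    schedule = dataset.schedule
    rows = []
    for rec in schedule.itertuples():
        traces = dataset.traces[(rec.animal, rec.stage, rec.trial)]
        metrics = trial_trace_metrics(traces, dataset.protocol, parameters)
        for p, m in metrics.items():
            rows.append({
                "animal": rec.animal, "group": rec.group, "stage": rec.stage,
                "trial": rec.trial, "parameter": p,
                "integral": m["integral_stim"],
                "integral_adaptive": m["integral_adaptive"],
                "integration_end_s": m["integration_end_s"],
                "truncated": m["truncated"],
            })
    table = pd.DataFrame(rows)
    out = []
    for p, sub in table.groupby("parameter"):
        # ABP/HR respond with a dip, so their integrals are negative
        out.append(response.baseline_normalize(
            sub, value_col="integral", require_positive=p not in ("ABP", "HR")))
    return pd.concat(out, ignore_index=True)


def group_report(integrals: pd.DataFrame, parameter: str = "APC",
                 alpha: float = stats.ALPHA) -> dict:
    """Friedman-per-group / Kruskal-Wallis-per-stage report on the
    baseline-normalized integrals of one parameter."""
    sub = integrals[integrals["parameter"] == parameter]
    return stats.experiment_report(sub, alpha=alpha)


def saline_divergence(integrals: pd.DataFrame, parameter: str = "APC",
                      alpha: float = stats.ALPHA,
                      saline: str = "saline") -> dict:
    """Qualitative group-divergence pattern of the normalized APC integrals:
    the saline response rises monotonically across infusion steps, exceeds
    every drug group after the last step, and the between-group contrast at
    the last step is significant."""
    report = group_report(integrals, parameter, alpha)
    wide = report["stage_means"]
    group_of = (integrals[integrals["parameter"] == parameter]
                .groupby("animal")["group"].first())
    stages = sorted(c for c in wide.columns if c > 0)
    last = stages[-1]
    med = {g: [float(wide.loc[group_of[group_of == g].index, s].median())
               for s in stages] for g in group_of.unique()}
    saline_rising = bool(np.all(np.diff(med[saline]) > 0) and med[saline][0] > 1.0)
    drugs = [g for g in med if g != saline]
    saline_dominates = all(med[saline][-1] > med[g][-1] for g in drugs)
    kw_last = report["kruskal"][last]
    return {
        "saline_rising": saline_rising,
        "saline_dominates": saline_dominates,
        "kw_last_stage_p": kw_last.p_value,
        "pattern": saline_rising and saline_dominates and kw_last.p_value < alpha,
        "stage_medians": med,
    }
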