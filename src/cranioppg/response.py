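"""Trial-response quantification: big-ROI selection, pre-stimulation
normalization and integral response metrics.

Each parameter trace (APC, OIS, ABP, HR) is normalized to its mean over the
pre-stimulation phase (first 20 s), expressed as a percentage with the
pre-stimulation level at 100%.  Two integrals of (value - 100%) quantify
the response: a fixed-window integral over the stimulation phase
(20-35 s) and an adaptive integral from 20 s until the trace returns into
the pre-stimulation band (+-2 SD, sustained for a hold window).  Integrals
are finally normalized per animal to the mean of its three baseline trials.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import APCMap, BigROISelection, NormalizedTrace, QCResult, TrialResponse
from .synth.kinetics import TrialProtocol

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Big ROI selection
# --------------------------------------------------------------------------

def select_big_rois(apc_map_at_stim: APCMap, electrode_xy: np.ndarray,
                    k: int = 6, roi_px: int = 27) -> BigROISelection:
    """Greedy selection of k disjoint 27x27-px windows maximizing mean APC.

    Candidate windows are anchored on the APC tile grid.  Among the selected
    windows, the two whose centers are nearest the electrode midpoint are
    flagged representative (ties broken toward higher APC).  Deterministic:
    equal scores resolve in row-major order.
    """
    tile = apc_map_at_stim.tile_px
    m = roi_px // tile  # tiles per ROI side
    vals = np.where(apc_map_at_stim.mask, apc_map_at_stim.values, np.nan)
    nh, nw = vals.shape
    if nh < m or nw < m:
        raise ValueError("frame too small for a single big ROI")
    # mean APC of every candidate window via a summed-area table
    filled = np.nan_to_num(vals)
    sat = np.pad(filled.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    score = (sat[m:, m:] - sat[:-m, m:] - sat[m:, :-m] + sat[:-m, :-m]) / (m * m)
    taken = np.zeros_like(score, dtype=bool)
    origins: list[tuple[int, int]] = []
    scores: list[float] = []
    order = np.argsort(-score, axis=None, kind="stable")  # ties: row-major
    for flat in order:
        if len(origins) == k:
            break
        r, c = np.unravel_index(flat, score.shape)
        if taken[max(r - m + 1, 0):r + m, max(c - m + 1, 0):c + m].any():
            continue
        taken[r, c] = True
        origins.append((int(r * tile), int(c * tile)))
        scores.append(float(score[r, c]))
    if len(origins) < k:
        raise ValueError(f"frame too small for {k} disjoint {roi_px}x{roi_px} ROIs")
    center = np.asarray(electrode_xy, dtype=float).reshape(-1, 2).mean(axis=0)
    centers = np.array(origins) + roi_px / 2.0
    dist = np.hypot(*(centers - center).T)
    # nearest two; ties toward higher APC
    rank = sorted(range(k), key=lambda i: (dist[i], -scores[i]))
    return BigROISelection(origins=origins, representative=sorted(rank[:2]),
                           roi_px=roi_px,
                           selection_time_s=apc_map_at_stim.timestamp_s)


# --------------------------------------------------------------------------
# Normalization and integrals
# --------------------------------------------------------------------------

def normalize_trace(t_s: np.ndarray, values: np.ndarray, protocol: TrialProtocol,
                    parameter: str = "") -> NormalizedTrace:
    """Express a trace in % of its pre-stimulation mean (first 20 s)."""
    t_s = np.asarray(t_s, dtype=float)
    values = np.asarray(values, dtype=float)
    pre = values[t_s < protocol.stim_onset_s]
    if pre.size < 2:
        raise ValueError("pre-stimulation phase must contain at least 2 samples")
    mean = pre.mean()
    if mean <= 0:
        raise ValueError(f"non-positive pre-stimulation mean for {parameter or 'trace'}")
    norm = values * (100.0 / mean)
    sd = float(norm[t_s < protocol.stim_onset_s].std(ddof=1))
    return NormalizedTrace(parameter=parameter, t_s=t_s, values=norm,
                           prestim_sd_pct=sd, pre_s=protocol.stim_onset_s)


def _trapz_between(t: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of v(t) over [a, b], interpolating the ends."""
    if a >= b:
        return 0.0
    inside = (t > a) & (t < b)
    ta = np.concatenate([[a], t[inside], [b]])
    va = np.concatenate([[np.interp(a, t, v)], v[inside], [np.interp(b, t, v)]])
    return float(np.trapezoid(va, ta))


def integral_stim(trace: NormalizedTrace, protocol: TrialProtocol) -> float:
    """Fixed-window integral (%*s) of (value - 100%) over the stimulation
    phase, 20-35 s."""
    a, b = protocol.stim_onset_s, protocol.stim_end_s
    t, v = trace.t_s, trace.values
    if t[0] > a or t[-1] < b:
        raise ValueError("samples do not cover the 20-35 s window")
    dt = np.diff(t[(t >= a - 1e-9) & (t <= b + 1e-9)])
    if dt.size and dt.max() > 2.0 * np.median(np.diff(t)) + 1e-9:
        raise ValueError("gap larger than 2 sample intervals inside the window")
    return _trapz_between(t, v - 100.0, a, b)


def integral_adaptive(trace: NormalizedTrace, protocol: TrialProtocol,
                      hold_s: float = 1.0) -> tuple[float, float, bool]:
    """Adaptive integral from stimulation onset to the 2-SD return.

    The end is the first time >= the stimulation end at which the trace
    stays inside [100 - 2 SD, 100 + 2 SD] for ``hold_s`` seconds (SD from
    the trial's own normalized pre-stimulation samples); capped at the trial
    end with a truncation flag.  Returns (integral %*s, end_s, truncated).
    """
    t, v = trace.t_s, trace.values
    sd = trace.prestim_sd_pct
    band = 2.0 * sd if sd > 0 else 1e-9
    inside = np.abs(v - 100.0) <= band
    start = protocol.stim_end_s
    dt = float(np.median(np.diff(t)))
    hold_n = max(int(round(hold_s / dt)), 1)
    candidates = np.flatnonzero(inside & (t >= start))
    end_s, truncated = float(t[-1]), True
    for i in candidates:
        j = min(i + hold_n, t.size)
        if inside[i:j].all():
            end_s, truncated = float(t[i]), False
            break
    integral = _trapz_between(t, v - 100.0, protocol.stim_onset_s, end_s)
    return integral, end_s, truncated


def trial_response(traces: dict[str, NormalizedTrace], protocol: TrialProtocol,
                   trial_id: str = "", qc: QCResult | None = None,
                   hold_s: float = 1.0) -> list[TrialResponse]:
    """Integral metrics for every parameter trace of one trial."""
    out = []
    for parameter, nt in traces.items():
        fixed = integral_stim(nt, protocol)
        adaptive, end_s, truncated = integral_adaptive(nt, protocol, hold_s)
        out.append(TrialResponse(trial_id=trial_id, parameter=parameter,
                                 integral_stim=fixed, integral_adaptive=adaptive,
                                 integration_end_s=end_s, truncated=truncated,
                                 qc=qc))
    return out


def baseline_normalize(integrals: pd.DataFrame, value_col: str = "integral",
                       baseline_stage: int = 0,
                       require_positive: bool = True,
                       eps: float = 1e-12) -> pd.DataFrame:
    """Divide every integral by the animal's mean over its baseline trials.

    ``integrals`` needs columns (animal, stage, ...).  Animals whose
    baseline mean is non-positive are flagged and excluded (logged).  For
    parameters whose response is a dip (ABP, HR — negative integrals by
    construction) pass ``require_positive=False``: only near-zero
    (non-informative) baselines are then excluded, and the ratio keeps its
    meaning because baseline and response share the sign.
    """
    required = {"animal", "stage", value_col}
    if not required <= set(integrals.columns):
        raise ValueError(f"integrals table needs columns {sorted(required)}")
    base = (integrals[integrals["stage"] == baseline_stage]
            .groupby("animal")[value_col].mean())
    ok = base[base > eps] if require_positive else base[base.abs() > eps]
    dropped = sorted(set(base.index) - set(ok.index))
    if dropped:
        log.warning("excluding animals with non-positive baseline mean: %s", dropped)
    out = integrals[integrals["animal"].isin(ok.index)].copy()
    out["normalized_integral"] = out[value_col] / out["animal"].map(ok)
    return out
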