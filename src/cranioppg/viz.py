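"""Rendering helpers: APC map overlays, trial traces, group box plots.

All functions return the matplotlib figure and take an optional ``path`` to
save a PNG; they are deliberately thin — analysis results live in the data
structures, not in the figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import APCMap, BigROISelection, NormalizedTrace


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    return fig


def plot_apc_map(apc_map: APCMap, background: np.ndarray | None = None,
                 rois: BigROISelection | None = None, path=None,
                 vmax: float | None = None):
    """Pseudo-colored APC map, optionally over the cortex image with the
    selected big-ROI squares drawn on top."""
    fig, ax = plt.subplots(figsize=(6, 4))
    tile = apc_map.tile_px
    extent = (0, apc_map.values.shape[1] * tile, apc_map.values.shape[0] * tile, 0)
    if background is not None:
        ax.imshow(background, cmap="gray", interpolation="nearest")
    im = ax.imshow(np.where(apc_map.mask, apc_map.values, np.nan),
                   cmap="jet", interpolation="nearest", extent=extent,
                   alpha=0.7 if background is not None else 1.0, vmax=vmax)
    fig.colorbar(im, ax=ax, label="APC (%)")
    if rois is not None:
        for i, (r, c) in enumerate(rois.origins):
            rep = i in rois.representative
            ax.add_patch(plt.Rectangle((c, r), rois.roi_px, rois.roi_px,
                                       fill=False, lw=2 if rep else 1,
                                       edgecolor="red" if rep else "white"))
    ax.set_title(f"APC map at t = {apc_map.timestamp_s:.1f} s")
    return _save(fig, path)


def plot_normalized_traces(traces: dict[str, NormalizedTrace], stim_onset_s: float,
                           stim_end_s: float, path=None):
    """Trial time courses on the normalized (%) scale with the
    pre/stimulation/relaxation phases shaded."""
    fig, axes = plt.subplots(len(traces), 1, figsize=(7, 2.2 * len(traces)),
                             sharex=True)
    axes = np.atleast_1d(axes)
    for ax, (name, nt) in zip(axes, traces.items()):
        ax.axvspan(0, stim_onset_s, color="gold", alpha=0.2)
        ax.axvspan(stim_onset_s, stim_end_s, color="red", alpha=0.2)
        ax.axvspan(stim_end_s, nt.t_s[-1], color="violet", alpha=0.15)
        ax.plot(nt.t_s, nt.values, lw=1)
        ax.axhline(100.0, color="k", lw=0.5, ls="--")
        ax.set_ylabel(f"{name} (%)")
    axes[-1].set_xlabel("trial time (s)")
    return _save(fig, path)


def plot_group_boxes(normalized: pd.DataFrame, path=None,
                     value_col: str = "normalized_integral"):
    """Median/IQR box plots of baseline-normalized integrals per stage and
    group (one panel per parameter)."""
    params = sorted(normalized["parameter"].unique())
    groups = sorted(normalized["group"].unique())
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3.5),
                             squeeze=False)
    width = 0.8 / len(groups)
    for ax, p in zip(axes[0], params):
        sub = normalized[normalized["parameter"] == p]
        stages = sorted(sub["stage"].unique())
        for gi, g in enumerate(groups):
            data = [sub[(sub["group"] == g) & (sub["stage"] == s)][value_col]
                    .dropna().to_numpy() for s in stages]
            pos = np.arange(len(stages)) + (gi - (len(groups) - 1) / 2) * width
            ax.boxplot(data, positions=pos, widths=width * 0.9,
                       tick_labels=[""] * len(stages))
        ax.set_xticks(np.arange(len(stages)))
        ax.set_xticklabels(["baseline"] + [f"step {s}" for s in stages[1:]])
        ax.set_title(p)
        ax.set_ylabel("normalized integral")
    return _save(fig, path)
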