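"""Segment-wise gradient (optical-flow) motion compensation.

The frame is tiled into 16 x 16 px segments and, for every frame, the
lateral offset of each segment relative to a fixed reference frame (the
first frame of the trial) is estimated with the classic single-step
gradient method: the least-squares solution of the brightness-constancy
constraint grad(I_ref) . d + (I_i - I_ref) = 0 over the segment's pixels.
The motion-related intensity component grad(I_ref) . d is then subtracted
from each pixel — an additive correction rather than a geometric re-warp.

Segments whose 2x2 normal matrix is ill-conditioned (untextured tissue) are
flagged and pass through unchanged, as are offsets beyond a configured
maximum.  Offsets are estimated independently per frame against the fixed
reference, never chained, so estimation errors do not accumulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import VideoRecording

log = logging.getLogger(__name__)

DEFAULT_SEGMENT_PX = 16


@dataclass
class SegmentGrid:
    """Non-overlapping tiling of the frame into ~segment_px square segments;
    edge segments may be smaller when dimensions are not multiples."""

    height_px: int
    width_px: int
    segment_px: int = DEFAULT_SEGMENT_PX

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0 or self.segment_px <= 0:
            raise ValueError("dimensions and segment size must be positive")

    @property
    def row_edges(self) -> np.ndarray:
        return np.append(np.arange(0, self.height_px, self.segment_px), self.height_px)

    @property
    def col_edges(self) -> np.ndarray:
        return np.append(np.arange(0, self.width_px, self.segment_px), self.width_px)

    @property
    def n_rows(self) -> int:
        return len(self.row_edges) - 1

    @property
    def n_cols(self) -> int:
        return len(self.col_edges) - 1

    @property
    def n_segments(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def origins(self) -> list[tuple[int, int]]:
        return [(int(r), int(c)) for r in self.row_edges[:-1] for c in self.col_edges[:-1]]

    def segment_of(self, row: int, col: int) -> tuple[int, int]:
        return (int(np.searchsorted(self.row_edges, row, "right") - 1),
                int(np.searchsorted(self.col_edges, col, "right") - 1))


def make_grid(height_px: int, width_px: int, segment_px: int = DEFAULT_SEGMENT_PX) -> SegmentGrid:
    if max(height_px, width_px) < segment_px:
        log.warning("frame smaller than one %d px segment in both axes", segment_px)
    return SegmentGrid(height_px=height_px, width_px=width_px, segment_px=segment_px)


@dataclass
class MotionField:
    """Per-frame, per-segment lateral offsets d = (dy, dx) in pixels."""

    d: np.ndarray  # (T, n_rows, n_cols, 2) sub-pixel offsets
    flagged: np.ndarray  # (T, n_rows, n_cols) bool, ill-conditioned/over-limit
    grid: SegmentGrid
    reference: int = 0

    def to_frame(self) -> pd.DataFrame:
        t, r, c = np.meshgrid(np.arange(self.d.shape[0]), np.arange(self.d.shape[1]),
                              np.arange(self.d.shape[2]), indexing="ij")
        return pd.DataFrame({
            "frame": t.ravel(), "seg_row": r.ravel(), "seg_col": c.ravel(),
            "dy": self.d[..., 0].ravel(), "dx": self.d[..., 1].ravel(),
            "flag": self.flagged.ravel(),
        })


def _reference_gradients(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # central differences, one-sided at borders
    gy, gx = np.gradient(ref.astype(np.float64))
    return gy, gx


def _segment_sums(arr: np.ndarray, grid: SegmentGrid) -> np.ndarray:
    """Sum over each segment; works for (H, W) or (T, H, W) input."""
    s = np.add.reduceat(arr, grid.row_edges[:-1], axis=-2)
    return np.add.reduceat(s, grid.col_edges[:-1], axis=-1)


def estimate_offsets(frames: VideoRecording, grid: SegmentGrid | None = None,
                     reference: int = 0, max_offset_px: float = 8.0,
                     cond_threshold: float = 1e3, eig_floor_frac: float = 1e-6,
                     cardiac_window_frames: int | None = None,
                     chunk: int = 200) -> MotionField:
    """Estimate per-segment offsets of every frame against a reference frame.

    Solves, per segment, the least-squares gradient-constraint system
    sum( (grad I_ref . d + alpha I_ref + beta + (I_i - I_ref))^2 ) -> min.
    The per-segment gain/offset nuisance terms (alpha, beta) matter on
    photoplethysmographic data: blood-volume and pulse signals change a
    segment's brightness without moving its pattern, and without these
    terms they masquerade as motion — compensation would then strip the
    very pulse signal being measured.  Eliminating the nuisance unknowns
    is equivalent to centering the gradients within each segment and
    orthogonalizing them against the centered reference image.

    Segments whose reduced 2x2 normal matrix has condition number above
    ``cond_threshold`` or smallest eigenvalue below ``eig_floor_frac``
    times the segment's mean squared gradient are flagged with d = 0, as
    are solutions with |d| > ``max_offset_px``.

    ``cardiac_window_frames`` (the median R-R interval in frames, see
    :func:`cranioppg.ppg.dc_window_frames`) additionally decorrelates the
    offset time series from the field-mean cardiac waveform, removing
    residual pulse leakage from segments where the pulse pattern is not
    proportional to the local reference image.  It is skipped on stacks
    shorter than four cardiac windows.
    """
    grid = grid or make_grid(*frames.shape)
    if not 0 <= reference < frames.n_frames:
        raise ValueError("reference frame index out of range")
    if (grid.height_px, grid.width_px) != frames.shape:
        raise ValueError("grid does not match frame shape")

    ref = frames.frames[reference].astype(np.float64)
    gy, gx = _reference_gradients(ref)
    npix = _segment_sums(np.ones_like(ref), grid)
    row_idx = np.searchsorted(grid.row_edges, np.arange(grid.height_px), "right") - 1
    col_idx = np.searchsorted(grid.col_edges, np.arange(grid.width_px), "right") - 1

    def _center(g: np.ndarray) -> np.ndarray:
        seg_mean = _segment_sums(g, grid) / npix
        return g - seg_mean[row_idx][:, col_idx]

    gy, gx, ic = _center(gy), _center(gx), _center(ref)
    ii = _segment_sums(ic * ic, grid)
    for g in (gy, gx):  # project out the per-segment gain direction
        coef = _segment_sums(g * ic, grid) / np.maximum(ii, 1e-12)
        g -= coef[row_idx][:, col_idx] * ic
    # reduced normal matrix per segment (depends on the reference only)
    a11 = _segment_sums(gy * gy, grid)
    a12 = _segment_sums(gy * gx, grid)
    a22 = _segment_sums(gx * gx, grid)
    tr, det = a11 + a22, a11 * a22 - a12 * a12
    disc = np.sqrt(np.maximum(tr * tr / 4 - det, 0.0))
    eig_min, eig_max = tr / 2 - disc, tr / 2 + disc
    msg = (a11 + a22) / npix  # mean squared (centered) gradient per segment
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(eig_min > 0, eig_max / eig_min, np.inf)
    ill = (cond > cond_threshold) | (eig_min < eig_floor_frac * msg) | (det <= 0)
    if ill.all():
        log.warning("all segments ill-conditioned (constant reference frame?)")

    n = frames.n_frames
    d = np.zeros((n, grid.n_rows, grid.n_cols, 2))
    flagged = np.zeros((n, grid.n_rows, grid.n_cols), dtype=bool)
    flagged[:] = ill[None]
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        diff = frames.frames[lo:hi].astype(np.float64) - ref[None]
        b1 = -_segment_sums(gy[None] * diff, grid)
        b2 = -_segment_sums(gx[None] * diff, grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            dy = (a22[None] * b1 - a12[None] * b2) / det[None]
            dx = (a11[None] * b2 - a12[None] * b1) / det[None]
        d[lo:hi, ..., 0] = np.nan_to_num(dy, nan=0.0, posinf=0.0, neginf=0.0)
        d[lo:hi, ..., 1] = np.nan_to_num(dx, nan=0.0, posinf=0.0, neginf=0.0)

    if cardiac_window_frames and n >= 4 * cardiac_window_frames:
        from scipy.ndimage import uniform_filter1d
        gm = frames.frames.reshape(n, -1).mean(axis=1).astype(np.float64)
        r_ac = gm - uniform_filter1d(gm, int(cardiac_window_frames), mode="reflect")
        r_ac -= r_ac.mean()
        denom = float(np.dot(r_ac, r_ac))
        if denom > 0:
            flat = d.reshape(n, -1)
            flat -= np.outer(r_ac, (r_ac[:, None] * flat).sum(axis=0) / denom)

    flagged |= np.hypot(d[..., 0], d[..., 1]) > max_offset_px
    d[flagged] = 0.0
    return MotionField(d=d, flagged=flagged, grid=grid, reference=reference)


def compensate(frames: VideoRecording, field: MotionField,
               grid: SegmentGrid | None = None) -> VideoRecording:
    """Subtract the motion-related component grad(I_ref) . d per segment.

    Pixels in flagged segments pass through unchanged (their d is 0).
    Output frames are float; re-quantization happens only on export.
    """
    grid = grid or field.grid
    if (grid.height_px, grid.width_px) != frames.shape:
        raise ValueError("grid does not match frame shape")
    if field.d.shape[:3] != (frames.n_frames, grid.n_rows, grid.n_cols):
        raise ValueError("motion field does not match frames/grid")

    ref = frames.frames[field.reference].astype(np.float64)
    gy, gx = _reference_gradients(ref)
    gy32, gx32 = gy.astype(np.float32), gx.astype(np.float32)
    # expand per-segment offsets to pixel maps, chunked over frames
    row_idx = np.searchsorted(grid.row_edges, np.arange(grid.height_px), "right") - 1
    col_idx = np.searchsorted(grid.col_edges, np.arange(grid.width_px), "right") - 1
    corrected = np.empty(frames.frames.shape, dtype=np.float32)
    for lo in range(0, frames.n_frames, 256):
        hi = min(lo + 256, frames.n_frames)
        d_px = field.d[lo:hi][:, row_idx][:, :, col_idx].astype(np.float32)
        # I_i ~ I_ref - grad(I_ref) . d for a content shift d, so the
        # motion-related component is -grad(I_ref) . d; subtracting it
        # means adding grad(I_ref) . d back
        corrected[lo:hi] = frames.frames[lo:hi] + (
            gy32[None] * d_px[..., 0] + gx32[None] * d_px[..., 1])
    return frames.copy_with(corrected)
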