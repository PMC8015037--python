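"""Core data containers shared across the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# physiological guards on R-R intervals (seconds), configurable per call
MIN_RR_S = 60.0 / 1000.0  # 1000 bpm
MAX_RR_S = 2.0  # 30 bpm


@dataclass
class VideoRecording:
    """A timestamped grayscale frame stack.

    ``frames`` has shape (T, H, W).  Pixel values live on the camera's
    10-bit scale (0-1023) but are carried as floats internally; quantization
    to 16-bit containers happens only on export.
    """

    frames: np.ndarray
    frame_rate_hz: float
    t0: float = 0.0
    pixel_pitch_um: float = float("nan")
    bit_depth: int = 10
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def max_count(self) -> int:
        return (1 << self.bit_depth) - 1

    def copy_with(self, frames: np.ndarray) -> "VideoRecording":
        return VideoRecording(
            frames=frames,
            frame_rate_hz=self.frame_rate_hz,
            t0=self.t0,
            pixel_pitch_um=self.pixel_pitch_um,
            bit_depth=self.bit_depth,
            meta=dict(self.meta),
        )


@dataclass
class SampledTrace:
    """A regularly sampled scalar signal (ECG, ABP, HR, APC/OIS series)."""

    values: np.ndarray
    rate_hz: float
    t0: float = 0.0
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz


@dataclass
class RPeakSeries:
    """Strictly increasing ECG R-peak times on the video clock."""

    times_s: np.ndarray
    source: str = "detected"  # "detected" | "provided"
    gap_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("R-peak times must be 1-D")
        if self.times_s.size >= 2:
            rr = np.diff(self.times_s)
            if np.any(rr <= 0):
                raise ValueError("R-peak times must be strictly increasing")

    def validate_physiology(self, min_rr_s: float = MIN_RR_S, max_rr_s: float = MAX_RR_S) -> None:
        rr = self.rr_intervals_s
        if rr.size and (rr.min() <= min_rr_s or rr.max() >= max_rr_s):
            raise ValueError(
                f"R-R intervals outside physiological range "
                f"({rr.min():.4f}-{rr.max():.4f} s vs ({min_rr_s}, {max_rr_s}))"
            )

    @property
    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.times_s)

    @property
    def n_peaks(self) -> int:
        return int(self.times_s.size)

    def n_cycles(self) -> int:
        return max(self.n_peaks - 1, 0)


@dataclass
class PPGWaveform:
    """AC/DC photoplethysmographic waveform of one small (3x3 px) ROI."""

    roi_origin: tuple[int, int]
    t_s: np.ndarray
    ac_over_dc: np.ndarray
    dc: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.ac_over_dc = np.asarray(self.ac_over_dc, dtype=float)
        self.dc = np.asarray(self.dc, dtype=float)


@dataclass
class MeanPulse:
    """Ensemble-averaged cardiac pulse over ``n_cycles`` consecutive R-R
    intervals, resampled to ``phase.size`` points of one normalized cycle."""

    phase: np.ndarray
    values: np.ndarray
    n_cycles: int
    window_center_s: float


@dataclass
class APCMap:
    """Grid of APC values (%) for non-overlapping 3x3-px ROI tiles."""

    values: np.ndarray  # (H//3, W//3), percent
    mask: np.ndarray  # True where the tile is valid
    timestamp_s: float
    tile_px: int = 3


@dataclass
class OISMap:
    """Per-pixel optical intrinsic signal (%) relative to a reference frame."""

    values: np.ndarray
    mask: np.ndarray
    frame_index: int
    time_s: float
    reference_index: int = 0
    smoothing: str = "dc-filtered"


@dataclass
class QCResult:
    """Stimulation-contact quality gate on the OIS rise during stimulation."""

    trial_id: str
    ois_increase_percent: float
    threshold_percent: float = 7.0

    @property
    def passed(self) -> bool:
        return bool(self.ois_increase_percent >= self.threshold_percent)


@dataclass
class NormalizedTrace:
    """Trial time course expressed in % of its pre-stimulation mean."""

    parameter: str  # "APC" | "OIS" | "ABP" | "HR"
    t_s: np.ndarray
    values: np.ndarray  # percent; pre-stimulation mean == 100 by construction
    prestim_sd_pct: float
    pre_s: float

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TrialResponse:
    """Integral response metrics of one 120 s stimulation trial."""

    trial_id: str
    parameter: str
    integral_stim: float  # %*s over the fixed 20-35 s window
    integral_adaptive: float  # %*s from 20 s to the 2-SD return
    integration_end_s: float
    truncated: bool = False
    qc: Optional[QCResult] = None
    baseline_normalized_integral: float = float("nan")


@dataclass
class BigROISelection:
    """Six 27x27-px analysis windows; two electrode-adjacent ones flagged
    representative."""

    origins: list[tuple[int, int]]
    representative: list[int]  # indices into origins
    roi_px: int = 27
    selection_time_s: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.representative) != 2:
            raise ValueError("exactly two representative ROIs are required")
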