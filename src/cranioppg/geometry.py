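"""Field-of-view geometry of the cranial-window imaging setup.

The camera images a 16.3 x 10.4 mm^2 field at 752 x 480 px, i.e. a pixel
pitch of ~21.7 um.  Analysis uses two ROI sizes: small 3 x 3 px ROIs for
the pulse-amplitude (APC) map and big 27 x 27 px ROIs for trial time
courses; their physical sides are ~65 um and ~0.6 mm.
"""

from __future__ import annotations

FOV_WIDTH_MM: float = 16.3
FOV_HEIGHT_MM: float = 10.4
SENSOR_WIDTH_PX: int = 752
SENSOR_HEIGHT_PX: int = 480

SMALL_ROI_PX: int = 3
BIG_ROI_PX: int = 27


def pixel_pitch_um(fov_mm: float = FOV_WIDTH_MM, n_px: int = SENSOR_WIDTH_PX) -> float:
    """Physical size of one pixel in micrometres."""
    if n_px <= 0 or fov_mm <= 0:
        raise ValueError("field of view and pixel count must be positive")
    return fov_mm * 1000.0 / n_px


def roi_side_um(roi_px: int, fov_mm: float = FOV_WIDTH_MM, n_px: int = SENSOR_WIDTH_PX) -> float:
    """Physical side length (um) of a square ROI of ``roi_px`` pixels."""
    if roi_px <= 0:
        raise ValueError("ROI size must be positive")
    return roi_px * pixel_pitch_um(fov_mm, n_px)


def roi_side_mm(roi_px: int, fov_mm: float = FOV_WIDTH_MM, n_px: int = SENSOR_WIDTH_PX) -> float:
    """Physical side length (mm) of a square ROI of ``roi_px`` pixels."""
    return roi_side_um(roi_px, fov_mm, n_px) / 1000.0
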