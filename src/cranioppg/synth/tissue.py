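"""Synthetic cortical tissue seen through a closed cranial window.

The model captures what the downstream analysis needs from the green-light
reflectance image: a textured parenchyma background, a few dark vessel
paths with class-specific pulsatility (arteries pulsate much more strongly
than veins), and a pair of stimulation-electrode coordinates adjacent to an
artery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

BACKGROUND, ARTERY, VEIN = 0, 1, 2


@dataclass
class TissueModel:
    height_px: int
    width_px: int
    pixel_pitch_um: float
    vessel_mask: np.ndarray  # per-pixel label {0 background, 1 artery, 2 vein}
    baseline_intensity: np.ndarray  # mean counts, 10-bit scale
    artery_pulsatility: float
    vein_pulsatility: float
    background_pulsatility: float
    electrode_xy: np.ndarray  # (2, 2) array of (row, col) pixel coordinates
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_intensity.min() < 0 or self.baseline_intensity.max() > 1023:
            raise ValueError("baseline intensity must stay on the 10-bit scale")
        if not (self.artery_pulsatility > self.vein_pulsatility >= 0):
            raise ValueError("artery pulsatility must exceed vein pulsatility >= 0")
        ey, ex = self.electrode_xy[:, 0], self.electrode_xy[:, 1]
        if np.any(ey < 0) or np.any(ey >= self.height_px) or np.any(ex < 0) or np.any(ex >= self.width_px):
            raise ValueError("electrodes must lie within the image")

    @property
    def pulsatility_map(self) -> np.ndarray:
        """Fractional AC/DC amplitude a(p) per pixel."""
        a = np.full(self.vessel_mask.shape, self.background_pulsatility, dtype=np.float32)
        a[self.vessel_mask == ARTERY] = self.artery_pulsatility
        a[self.vessel_mask == VEIN] = self.vein_pulsatility
        return a

    @property
    def electrode_center(self) -> tuple[float, float]:
        return tuple(self.electrode_xy.mean(axis=0))


def _vessel_path(rng: np.random.Generator, width_px: int, height_px: int,
                 row0: float, wiggle: float = 0.35) -> np.ndarray:
    """Smooth row trajectory of a roughly horizontal vessel across the field."""
    steps = rng.standard_normal(width_px) * wiggle
    path = row0 + ndimage.gaussian_filter1d(np.cumsum(steps), sigma=width_px / 12)
    return np.clip(path, 2, height_px - 3)


def _paint(mask: np.ndarray, path: np.ndarray, half_width: float, label: int) -> None:
    h = mask.shape[0]
    rows = np.arange(h)[:, None]
    mask[np.abs(rows - path[None, :]) <= half_width] = label


def make_tissue(seed: int, height_px: int = 120, width_px: int = 188,
                pixel_pitch_um: float = 21.7,
                artery_pulsatility: float = 0.02,
                vein_pulsatility: float = 0.005,
                background_pulsatility: float = 0.002,
                mean_counts: float = 600.0) -> TissueModel:
    """Deterministically generate a tissue model for a given seed.

    The field hosts two arteries and two veins crossing it, plus textured
    parenchyma (needed so that gradient-based motion estimation has
    contrast).  Raises if the field cannot host a 27x27-px big ROI.
    """
    if height_px < 48 or width_px < 48:
        raise ValueError("field must be at least 48 x 48 px to host a 27x27 ROI")
    rng = np.random.default_rng(seed)

    mask = np.zeros((height_px, width_px), dtype=np.uint8)
    # veins first so arteries overwrite at crossings (arteries run on top)
    for frac in (0.30, 0.72):
        row0 = height_px * (frac + 0.06 * rng.uniform(-1, 1))
        _paint(mask, _vessel_path(rng, width_px, height_px, row0), 3.0, VEIN)
    artery_paths = []
    for frac in (0.18, 0.55):
        row0 = height_px * (frac + 0.06 * rng.uniform(-1, 1))
        path = _vessel_path(rng, width_px, height_px, row0)
        artery_paths.append(path)
        _paint(mask, path, 2.0, ARTERY)

    texture = ndimage.gaussian_filter(rng.standard_normal((height_px, width_px)), 4.0)
    texture *= 60.0 / max(texture.std(), 1e-9)
    baseline = np.full((height_px, width_px), mean_counts, dtype=np.float32) + texture
    baseline[mask == ARTERY] *= 0.62  # blood absorbs green light
    baseline[mask == VEIN] *= 0.52
    baseline = ndimage.gaussian_filter(baseline, 1.0)  # soft vessel edges
    baseline = np.clip(baseline, 0, 1023).astype(np.float32)

    # electrodes straddle the second artery around mid-field
    path = artery_paths[-1]
    col = int(width_px * 0.5)
    row = float(path[col])
    electrode_xy = np.array([
        [int(np.clip(row - 6, 0, height_px - 1)), col - 6],
        [int(np.clip(row + 6, 0, height_px - 1)), col + 6],
    ])

    return TissueModel(
        height_px=height_px, width_px=width_px, pixel_pitch_um=pixel_pitch_um,
        vessel_mask=mask, baseline_intensity=baseline,
        artery_pulsatility=artery_pulsatility, vein_pulsatility=vein_pulsatility,
        background_pulsatility=background_pulsatility,
        electrode_xy=electrode_xy, seed=seed,
    )
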