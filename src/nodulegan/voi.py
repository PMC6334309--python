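"""Volume-of-interest extraction.

The VOI is a cube centered on the annotated nodule with physical side equal
to twice the nodule's maximum diameter, capturing the nodule and its
immediate surroundings. The cube is resampled to an isotropic grid
(trilinear interpolation) so downstream oblique reslicing preserves angles;
the voxel count per side is forced odd so the nodule center falls exactly on
the central lattice point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, NoduleAnnotation

DEFAULT_PAD_INTENSITY = -1024.0  # air; nodules near the pleura abut volume edges


@dataclass
class VOICube:
    """Isotropic cube of intensities centered on one nodule."""

    data: np.ndarray  # (side, side, side), axes (x, y, z)
    resolution_mm: float
    source_case: str
    label: str
    pad_intensity: float = DEFAULT_PAD_INTENSITY

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        s = self.data.shape
        if len(s) != 3 or len(set(s)) != 1:
            raise ValueError(f"VOI must be a cube, got shape {s}")
        if s[0] % 2 != 1:
            raise ValueError(f"VOI side must be odd, got {s[0]}")

    @property
    def side_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def side_mm(self) -> float:
        return self.side_voxels * self.resolution_mm

    @property
    def center_index(self) -> int:
        return (self.side_voxels - 1) // 2


def _nearest_odd(x: float) -> int:
    """Nearest odd integer to x, ties resolved upward (never truncates the VOI)."""
    lo = int(np.floor(x))
    lo = lo if lo % 2 == 1 else lo - 1
    hi = lo + 2
    if x - lo < hi - x:
        return max(lo, 1)
    return hi


def extract_voi(
    volume: CTVolume,
    annotation: NoduleAnnotation,
    target_resolution: float = 1.0,
    pad_intensity: float = DEFAULT_PAD_INTENSITY,
) -> VOICube:
    """Extract the 2x-diameter cube around ``annotation`` at isotropic resolution.

    Regions sampled outside the source volume are filled with
    ``pad_intensity`` (air density by default).
    """
    if target_resolution <= 0:
        raise ValueError(f"target_resolution must be > 0, got {target_resolution}")
    if not volume.contains_mm(annotation.center_mm):
        raise ValueError(
            f"annotation center {annotation.center_mm} outside volume bounds {volume.extent_mm()}"
        )
    side_mm_nominal = 2.0 * annotation.max_diameter_mm
    side = _nearest_odd(side_mm_nominal / target_resolution)
    c = (side - 1) / 2.0
    offsets = (np.arange(side) - c) * target_resolution  # mm, relative to nodule center

    center = np.asarray(annotation.center_mm)
    ox, oy, oz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts_mm = np.stack([ox + center[0], oy + center[1], oz + center[2]])
    # mm -> continuous voxel coordinates of the source grid
    spacing = np.asarray(volume.spacing)[:, None, None, None]
    origin = np.asarray(volume.origin)[:, None, None, None]
    coords = (pts_mm - origin) / spacing

    cube = ndimage.map_coordinates(
        volume.data.astype(np.float64), coords, order=1, mode="constant", cval=pad_intensity
    )
    return VOICube(
        data=cube,
        resolution_mm=float(target_resolution),
        source_case=annotation.case_id,
        label=annotation.label,
        pad_intensity=float(pad_intensity),
    )
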