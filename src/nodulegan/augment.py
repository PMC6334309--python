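"""Oblique-section augmentation of nodule VOIs.

From each VOI a stack of 2-D sections is sampled: the axial plane through the
cube center, tilted about an in-plane axis over a grid of angles (default
-40 deg to +40 deg in 5 deg steps). Each section is then expanded by the
eight dihedral symmetries of the square (rotations by 0/90/180/270 degrees,
with and without a horizontal flip), which are exact lattice operations.

With the default configuration - the 16 non-zero tilt angles about each of
the two in-plane axes (32 orientations) times 8 symmetries - every nodule
yields exactly 256 patches. A "faithful text" configuration (17 angles
including 0 deg about a single axis, 8 symmetries -> 136 patches) is also
provided; see :meth:`AugmentConfig.faithful_text`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage

from .voi import VOICube

DIHEDRAL_OPS = ("r0", "r90", "r180", "r270", "r0f", "r90f", "r180f", "r270f")


@dataclass(frozen=True)
class SectionOrientation:
    """A section plane: the axial plane tilted by `angle_deg` about `tilt_axis`."""

    tilt_axis: str  # "x" or "y"
    angle_deg: float

    def __post_init__(self):
        if self.tilt_axis not in ("x", "y"):
            raise ValueError(f"tilt_axis must be 'x' or 'y', got {self.tilt_axis!r}")
        if not (-90.0 <= self.angle_deg <= 90.0):
            raise ValueError(f"angle {self.angle_deg} outside [-90, 90]")


AXIAL = "axial"


@dataclass
class AugmentConfig:
    angle_min: float = -40.0
    angle_max: float = 40.0
    angle_step: float = 5.0
    tilt_axes: tuple[str, ...] = ("x", "y")
    include_axial: bool = False
    symmetry_ops: tuple[str, ...] = DIHEDRAL_OPS

    def __post_init__(self):
        if self.angle_step <= 0:
            raise ValueError("angle_step must be > 0")
        span = self.angle_max - self.angle_min
        if abs(round(span / self.angle_step) * self.angle_step - span) > 1e-9:
            raise ValueError(f"(angle_max - angle_min) = {span} not divisible by step {self.angle_step}")
        unknown = set(self.symmetry_ops) - set(DIHEDRAL_OPS)
        if unknown:
            raise ValueError(f"unknown symmetry ops {sorted(unknown)}")
        if not set(self.tilt_axes) <= {"x", "y"}:
            raise ValueError(f"tilt_axes must be a subset of ('x','y'), got {self.tilt_axes}")

    def orientations(self) -> list[Union[SectionOrientation, str]]:
        """Orientation list: non-zero tilts per axis, plus optionally the pure axial."""
        n = int(round((self.angle_max - self.angle_min) / self.angle_step))
        angles = [self.angle_min + i * self.angle_step for i in range(n + 1)]
        out: list[Union[SectionOrientation, str]] = []
        if self.include_axial:
            out.append(AXIAL)
        for axis in self.tilt_axes:
            for a in angles:
                if abs(a) > 1e-12:
                    out.append(SectionOrientation(axis, a))
        return out

    @classmethod
    def faithful_text(cls) -> "AugmentConfig":
        """Single tilt axis, all 17 angles incl. 0 deg: 136 patches per nodule."""
        return cls(tilt_axes=("x",), include_axial=True)


@dataclass
class PatchImage:
    """A 2-D grayscale section with full provenance."""

    pixels: np.ndarray
    source_case: str
    label: str
    orientation: Union[SectionOrientation, str]
    symmetry_op: str = "r0"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"patch must be square 2-D, got shape {self.pixels.shape}")


def oblique_slice(voi: VOICube, orientation: Union[SectionOrientation, str]) -> PatchImage:
    """Sample the section plane through the VOI center by trilinear interpolation.

    The plane is the axial (constant-z) plane rotated by ``angle`` about the
    chosen in-plane axis through the cube center; at 0 deg (or ``"axial"``)
    it reproduces the central axial slice exactly. Samples falling outside
    the cube take the VOI's padding intensity.
    """
    side = voi.side_voxels
    c = voi.center_index
    if orientation == AXIAL:
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
    else:
        theta = np.deg2rad(orientation.angle_deg)
        if orientation.tilt_axis == "x":
            # rotate about x: e_x fixed, e_y tilts into z
            u = np.array([1.0, 0.0, 0.0])
            v = np.array([0.0, np.cos(theta), np.sin(theta)])
        else:
            # rotate about y: e_y fixed, e_x tilts into z
            u = np.array([np.cos(theta), 0.0, -np.sin(theta)])
            v = np.array([0.0, 1.0, 0.0])

    idx = np.arange(side) - c  # voxel units; VOI is isotropic
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    coords = np.empty((3, side, side))
    for d in range(3):
        coords[d] = c + ii * u[d] + jj * v[d]
    pix = ndimage.map_coordinates(
        voi.data.astype(np.float64), coords, order=1, mode="constant", cval=voi.pad_intensity
    )
    return PatchImage(pix, source_case=voi.source_case, label=voi.label, orientation=orientation)


def apply_dihedral(pixels: np.ndarray, op: str) -> np.ndarray:
    """Exact lattice symmetry of the square: optional horizontal flip, then rot90s."""
    if op not in DIHEDRAL_OPS:
        raise ValueError(f"unknown symmetry op {op!r}")
    out = np.fliplr(pixels) if op.endswith("f") else pixels
    k = {"r0": 0, "r90": 1, "r180": 2, "r270": 3}[op.rstrip("f")]
    return np.rot90(out, k).copy()


def dihedral_expand(patch: PatchImage, ops=DIHEDRAL_OPS) -> list[PatchImage]:
    """One output patch per symmetry op, provenance recording the op."""
    if patch.pixels.shape[0] != patch.pixels.shape[1]:
        raise ValueError("dihedral ops require a square patch")
    return [
        PatchImage(
            apply_dihedral(patch.pixels, op),
            source_case=patch.source_case,
            label=patch.label,
            orientation=patch.orientation,
            symmetry_op=op,
        )
        for op in ops
    ]


def augment_nodule(voi: VOICube, config: AugmentConfig | None = None) -> list[PatchImage]:
    """All sections x all symmetry ops for one VOI.

    Output count = len(orientations) x len(symmetry_ops); 32 x 8 = 256 with
    the defaults.
    """
    config = config or AugmentConfig()
    orientations = config.orientations()
    if not orientations:
        raise ValueError("empty orientation set")
    out: list[PatchImage] = []
    for orientation in orientations:
        section = oblique_slice(voi, orientation)
        out.extend(dihedral_expand(section, config.symmetry_ops))
    return out
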