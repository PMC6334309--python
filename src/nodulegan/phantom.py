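"""Synthetic CT phantom cohort with benign / malignant nodules.

Real biopsy-confirmed nodule CT datasets are small and rarely shareable, so
this module generates stand-in volumes carrying the morphological contrast a
benign/malignant classifier must exploit:

* **benign** — a smooth, near-spherical soft-tissue-density blob (Gaussian
  smoothed ellipsoid) in low-density lung background;
* **malignant** — the same core plus *spicula*: radial spikes extending past
  the core surface with linearly decaying intensity, and (optionally) pleural
  attachment to a high-intensity chest-wall plane.

Intensities live on an HU-like scale (lung ~ -800, soft tissue ~ +40) and
are clipped to [-1024, +400], so the same HU display window is meaningful
for phantom and real CT.

Reproducibility: ``generate_case`` consumes its PRNG in a fixed, documented
draw order (diameter, center, axis jitter, attachment, spicule count,
spicule directions, spicule lengths, noise), and ``generate_cohort`` derives
one integer seed per case from the master seed with a counter-based
``SeedSequence`` split, so cohorts are identical across platforms and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, NoduleAnnotation, LABELS

INTENSITY_CLIP = (-1024.0, 400.0)


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the synthetic cohort.

    Defaults give a 64 mm³ field of view at 1 mm isotropic voxels with
    nodules of 8-16 mm maximum diameter, so the 2x-diameter VOI always fits.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_background_intensity: float = -800.0
    nodule_intensity: float = 40.0
    noise_sigma: float = 20.0
    diameter_range_mm: tuple[float, float] = (8.0, 16.0)
    spicule_count_range: tuple[int, int] = (3, 8)
    spicule_length_fraction: float = 0.6
    pleural_attachment_prob: float = 0.3
    chest_wall: bool = True
    chest_wall_intensity: float = 30.0
    chest_wall_thickness_mm: float = 4.0

    def __post_init__(self):
        if self.diameter_range_mm[0] <= 0 or self.diameter_range_mm[1] < self.diameter_range_mm[0]:
            raise ValueError(f"invalid diameter_range_mm {self.diameter_range_mm}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.spicule_count_range[0] < 1 or self.spicule_count_range[1] < self.spicule_count_range[0]:
            raise ValueError(f"spicule_count_range min must be >= 1, got {self.spicule_count_range}")
        if not (0.0 <= self.pleural_attachment_prob <= 1.0):
            raise ValueError("pleural_attachment_prob must be in [0, 1]")
        extent = min((n - 1) * s for n, s in zip(self.volume_shape, self.voxel_spacing))
        if extent < 2.0 * self.diameter_range_mm[1]:
            raise ValueError(
                f"volume extent {extent:.1f} mm cannot contain a VOI of "
                f"2 x max diameter = {2 * self.diameter_range_mm[1]:.1f} mm"
            )


@dataclass
class PhantomCase:
    volume: CTVolume
    annotation: NoduleAnnotation
    seed: int
    details: dict = field(default_factory=dict)


def _mm_grids(config: PhantomConfig):
    axes = [np.arange(n) * s for n, s in zip(config.volume_shape, config.voxel_spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_case(config: PhantomConfig, label: str, seed: int) -> PhantomCase:
    """Generate one phantom case; bit-identical for a fixed (config, label, seed)."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)

    # -- PRNG draw order is part of the contract (see module docstring) --
    diameter = float(rng.uniform(*config.diameter_range_mm))
    u_center = rng.uniform(0.0, 1.0, 3)
    axis_jitter = rng.uniform(0.9, 1.1, 3)
    attach_draw = float(rng.random())

    radius = diameter / 2.0
    extent = np.array([(n - 1) * s for n, s in zip(config.volume_shape, config.voxel_spacing)])
    margin = diameter  # nodule + spicules stay inside
    center = margin + u_center * (extent - 2 * margin)

    # scale jitter so the largest semi-axis equals the drawn radius exactly
    semi = radius * axis_jitter / axis_jitter.max()

    attached = bool(
        label == "malignant" and config.chest_wall and attach_draw < config.pleural_attachment_prob
    )
    if attached:
        center[0] = config.chest_wall_thickness_mm + semi[0]

    spicules = []
    n_spicules = 0
    if label == "malignant":
        n_spicules = int(rng.integers(config.spicule_count_range[0], config.spicule_count_range[1] + 1))
        dirs = rng.normal(size=(n_spicules, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lengths = config.spicule_length_fraction * radius * rng.uniform(0.7, 1.3, n_spicules)
        spicules = list(zip(dirs, lengths))

    gx, gy, gz = _mm_grids(config)

    # chest wall plane at low x
    base = np.full(config.volume_shape, config.lung_background_intensity, dtype=np.float64)
    if config.chest_wall:
        base[gx <= config.chest_wall_thickness_mm] = config.chest_wall_intensity

    # smooth ellipsoidal core; edge softened by a Gaussian of 5% of diameter
    d2 = ((gx - center[0]) / semi[0]) ** 2 + ((gy - center[1]) / semi[1]) ** 2 + ((gz - center[2]) / semi[2]) ** 2
    indicator = (d2 <= 1.0).astype(np.float64)
    sigma_mm = 0.05 * diameter
    sigma_vox = [sigma_mm / s for s in config.voxel_spacing]
    weight = ndimage.gaussian_filter(indicator, sigma=sigma_vox)
    weight[d2 <= 0.5] = 1.0  # exact plateau deep inside the core
    np.clip(weight, 0.0, 1.0, out=weight)

    # spicules: line segments from the core surface outward, weight decaying
    # linearly from 1 at the base to 0 at the tip, stamped as small balls
    spike_radius_mm = 0.9
    min_sp = min(config.voxel_spacing)
    for direction, length in spicules:
        r_dir = 1.0 / np.sqrt(np.sum((direction / semi) ** 2))  # core radius along this ray
        n_steps = max(2, int(np.ceil(length / (0.5 * min_sp))))
        for t in np.linspace(0.0, 1.0, n_steps):
            p = center + direction * (r_dir + t * length)
            w_sp = 1.0 - t
            lo = np.maximum(0, np.floor((p - spike_radius_mm) / config.voxel_spacing)).astype(int)
            hi = np.minimum(config.volume_shape, np.ceil((p + spike_radius_mm) / config.voxel_spacing) + 1).astype(int)
            if np.any(lo >= hi):
                continue
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            dd = np.sqrt((gx[sl] - p[0]) ** 2 + (gy[sl] - p[1]) ** 2 + (gz[sl] - p[2]) ** 2)
            ball = np.where(dd <= spike_radius_mm, w_sp, 0.0)
            np.maximum(weight[sl], ball, out=weight[sl])

    vol = base * (1.0 - weight) + config.nodule_intensity * weight
    if config.noise_sigma > 0:
        vol = vol + rng.normal(0.0, config.noise_sigma, config.volume_shape)
    np.clip(vol, *INTENSITY_CLIP, out=vol)

    annotation = NoduleAnnotation(
        case_id=f"case_{label}_{seed}",
        center_mm=tuple(center),
        max_diameter_mm=diameter,
        label=label,
        isolated=not attached,
        seed=seed,
    )
    volume = CTVolume(vol, config.voxel_spacing, (0.0, 0.0, 0.0))
    details = {
        "diameter_mm": diameter,
        "semi_axes_mm": tuple(semi),
        "n_spicules": n_spicules,
        "attached": attached,
    }
    return PhantomCase(volume=volume, annotation=annotation, seed=int(seed), details=details)


def case_seeds(master_seed: int, n: int) -> list[int]:
    """Counter-based per-case seed derivation (portable, order-independent)."""
    return [int(np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0]) for i in range(n)]


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    config: PhantomConfig,
    seed: int,
) -> list[PhantomCase]:
    """Generate ``n_benign + n_malignant`` cases (benign first), deterministically."""
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("case counts must be >= 0")
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    seeds = case_seeds(seed, len(labels))
    cases = []
    for i, (label, case_seed) in enumerate(zip(labels, seeds)):
        case = generate_case(config, label, case_seed)
        case.annotation.case_id = f"case{i:03d}"
        cases.append(case)
    return cases


def boundary_shell_variance(case: PhantomCase) -> float:
    """Intensity variance on the shell just outside the nodule core.

    A brute-force separability feature: spicules cross this shell, so
    malignant cases show higher variance than smooth benign cores.
    """
    vol = case.volume
    r = case.annotation.max_diameter_mm / 2.0
    axes = [np.arange(n) * s for n, s in zip(vol.shape, vol.spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    c = case.annotation.center_mm
    dist = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
    shell = (dist >= 1.05 * r) & (dist <= 1.55 * r)
    return float(vol.data[shell].var())
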