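"""Shared intensity scaling and resizing.

All networks see intensities on a fixed [-1, 1] scale obtained by a linear
map of the HU display window [-1000, +400] (lung window); the map is
invertible and shared by the WGAN and the classifier so generated images and
real patches live on the same scale.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _resize

HU_WINDOW = (-1000.0, 400.0)


def hu_to_unit(x: np.ndarray) -> np.ndarray:
    """Linear map HU_WINDOW -> [-1, 1], clipped."""
    lo, hi = HU_WINDOW
    y = 2.0 * (np.asarray(x, dtype=np.float64) - lo) / (hi - lo) - 1.0
    return np.clip(y, -1.0, 1.0)


def unit_to_hu(y: np.ndarray) -> np.ndarray:
    lo, hi = HU_WINDOW
    return (np.asarray(y, dtype=np.float64) + 1.0) * (hi - lo) / 2.0 + lo


def resize_square(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a square image; identity when already at `size`."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape[0] == size and img.shape[1] == size:
        return img
    return _resize(img, (size, size), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
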