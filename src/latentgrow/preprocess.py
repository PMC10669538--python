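"""Raw image and click preprocessing.

CT slices arrive in Hounsfield-like units and are windowed to a fixed range
before normalisation to [0, 1]; MRI slices use a wider default window.
Images are plain 2-D float arrays, masks plain 2-D boolean arrays, and a
click is a (row, col, polarity) triple in 0-based pixel coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import InputError

# Default intensity windows (lo, hi) applied before [0, 1] normalisation.
CT_WINDOW = (-135.0, 215.0)
MRI_WINDOW = (100.0, 1000.0)


class Click(NamedTuple):
    row: int
    col: int
    positive: bool = True


def clip_normalize(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip to [lo, hi] then rescale linearly to [0, 1]."""
    if lo >= hi:
        raise InputError(f"window requires lo < hi, got ({lo}, {hi})")
    raw = np.asarray(raw, dtype=np.float64)
    return (np.clip(raw, lo, hi) - lo) / (hi - lo)


def resize(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize; output values stay within [0, 1]."""
    h, w = size
    if h < 16 or w < 16:
        raise InputError("target size must be at least 16 x 16")
    out = _sk_resize(np.asarray(image, dtype=np.float64), (h, w), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize keeping the mask binary."""
    out = _sk_resize(mask.astype(np.float64), size, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out > 0.5


def click_to_dot(click: Click, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a click as a closed Euclidean unit disk (center + 4-neighbours).

    This 5-pixel dot is the seed mask g0 of an interactive session; at image
    borders the disk is clipped.
    """
    h, w = shape
    r, c = int(click.row), int(click.col)
    if not (0 <= r < h and 0 <= c < w):
        raise InputError(f"click ({r}, {c}) outside image of shape {shape}")
    mask = np.zeros((h, w), dtype=bool)
    for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            mask[rr, cc] = True
    return mask


def render_mask(mask: np.ndarray) -> np.ndarray:
    """Binary mask as a {0, 1} intensity image (for encoding)."""
    return mask.astype(np.float64)


# ---------------------------------------------------------------------------
# File I/O: PNG (8/16-bit grayscale) and NIfTI slices.

def read_png(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG as floats in [0, 1]."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    peak = 65535.0 if arr.dtype == np.uint16 else 255.0
    return arr.astype(np.float64) / peak


def write_png(path: str | Path, image: np.ndarray) -> None:
    """Write an image in [0, 1] (or a boolean mask) as an 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.float64)
    data = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def read_nifti_slice(path: str | Path, slice_index: int) -> np.ndarray:
    """Raw (unwindowed) axial slice from a NIfTI volume."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim < 3:
        raise InputError("expected a 3-D NIfTI volume")
    if not (0 <= slice_index < vol.shape[2]):
        raise InputError(
            f"slice {slice_index} out of range for volume with "
            f"{vol.shape[2]} axial slices")
    return np.asarray(vol[:, :, slice_index], dtype=np.float64)


def load_image(path: str | Path, modality: str = "CT",
               slice_index: int = 0,
               window: tuple[float, float] | None = None) -> np.ndarray:
    """Read a PNG or NIfTI slice and window-normalise it to [0, 1].

    PNGs are assumed already in display range and only rescaled; NIfTI data
    is windowed with the modality default unless an explicit window is given.
    """
    path = Path(path)
    if path.suffix == ".png":
        return read_png(path)
    if window is None:
        window = MRI_WINDOW if modality.upper() == "MRI" else CT_WINDOW
    raw = read_nifti_slice(path, slice_index)
    return clip_normalize(raw, *window)
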