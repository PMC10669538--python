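"""Click-based refinement of an existing segmentation mask.

A positive click runs the full click-seeded growth again and unions the new
mask with the current one.  A negative click removes mask regions closer (in
the Gaussian-density sense) to the negative click than to any positive click:
mask pixels are partitioned by nearest click, each partition defines an
isotropic Gaussian whose sigma is the standard deviation of pixel distances
to its click, and every pixel where the negative density strictly exceeds the
best positive density is dropped.
"""

from __future__ import annotations

import numpy as np

from .autoencoder import AutoencoderWeights
from .diffusion_core import run_initial_segmentation
from .errors import InputError
from .preprocess import Click

SIGMA_FLOOR = 1.0   # pixels; keeps singleton-region densities finite


def region_distance_std(region: np.ndarray, center: Click,
                        floor: float = 0.0) -> float:
    """Population std of Euclidean distances from region pixels to the click."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise InputError("region is empty")
    rr, cc = np.nonzero(region)
    d = np.hypot(rr - center.row, cc - center.col)
    return max(float(d.std()), floor)


def gaussian_density_map(center: Click, sigma: float,
                         shape: tuple[int, int]) -> np.ndarray:
    """Isotropic 2-D Gaussian density (integral 1) centred at the click."""
    if sigma <= 0:
        raise InputError("sigma must be positive")
    rows = np.arange(shape[0])[:, None] - center.row
    cols = np.arange(shape[1])[None, :] - center.col
    d2 = rows ** 2 + cols ** 2
    return np.exp(-d2 / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)


def apply_positive_click(image: np.ndarray, mask: np.ndarray, click: Click,
                         weights: AutoencoderWeights,
                         **segmentation_kwargs) -> np.ndarray:
    """Grow a new mask from the click and union it with the current mask."""
    state = run_initial_segmentation(image, click, weights,
                                     **segmentation_kwargs)
    return np.asarray(mask, dtype=bool) | state.current_mask


def _nearest_click_partition(mask: np.ndarray,
                             clicks: list[Click]) -> np.ndarray:
    """Index of the nearest click for every mask pixel (ties: first click)."""
    rr, cc = np.nonzero(mask)
    d2 = np.stack([(rr - c.row) ** 2 + (cc - c.col) ** 2 for c in clicks])
    return d2.argmin(axis=0)


def apply_negative_click(mask: np.ndarray, positive_clicks: list[Click],
                         negative_click: Click
                         ) -> tuple[np.ndarray, bool]:
    """Remove the mask region dominated by the negative click's density.

    Returns (refined mask, emptied flag).  Ties keep the pixel — removal
    requires the negative density to strictly surpass every positive density.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("mask is empty")
    if not positive_clicks:
        raise InputError("at least one positive click is required")
    clicks = [negative_click] + list(positive_clicks)
    owner = _nearest_click_partition(mask, clicks)
    rr, cc = np.nonzero(mask)
    shape = mask.shape

    def _sigma(idx: int) -> float:
        sel = owner == idx
        if not sel.any():
            return SIGMA_FLOOR
        region = np.zeros(shape, dtype=bool)
        region[rr[sel], cc[sel]] = True
        return region_distance_std(region, clicks[idx], floor=SIGMA_FLOOR)

    neg_density = gaussian_density_map(negative_click, _sigma(0), shape)
    pos_density = np.full(shape, -np.inf)
    for i in range(1, len(clicks)):
        pos_density = np.maximum(
            pos_density, gaussian_density_map(clicks[i], _sigma(i), shape))
    refined = mask & ~(neg_density > pos_density)
    return refined, not refined.any()
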