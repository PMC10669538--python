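"""Click-seeded mask growth by latent feature mixing.

One growth step: (1) remap the image intensities by the density of values
around the current mask, (2) encode the remapped image and the mask rendered
as a {0,1} image, average the two latents, and decode — and likewise mix the
remapped image with an all-black reference image, (3) subtract the black-
reference reconstruction from the mask reconstruction (clamped at 0) and
binarise the difference with Otsu's threshold, keeping only connected
components that touch the previous mask.  Iterating from the 5-pixel click
dot grows the seed into the organ until two consecutive masks are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .autoencoder import AutoencoderWeights, LatentFeature, decode, encode
from .density_adjust import DEFAULT_DILATION_ITERATIONS, adjust_intensity
from .errors import DegenerateInputError, InputError
from .preprocess import Click, click_to_dot, render_mask

_EIGHT_CONN = np.ones((3, 3), dtype=bool)
DEFAULT_MAX_ITERATIONS = 50


def mix_features(f1: LatentFeature, f2: LatentFeature) -> LatentFeature:
    """Element-wise average of two latent features."""
    if f1.values.shape != f2.values.shape:
        raise InputError(
            f"latent shapes differ: {f1.values.shape} vs {f2.values.shape}")
    return LatentFeature(values=(f1.values + f2.values) / 2,
                         source_shape=f1.source_shape)


def _black_latent(shape: tuple[int, int],
                  weights: AutoencoderWeights) -> LatentFeature:
    """Latent of the all-black image, cached per weights object and shape."""
    cache = getattr(weights, "_black_latents", None)
    if cache is None:
        cache = weights._black_latents = {}
    if shape not in cache:
        cache[shape] = encode(np.zeros(shape), weights)
    return cache[shape]


def mixed_decode(image: np.ndarray, companion: np.ndarray,
                 weights: AutoencoderWeights) -> np.ndarray:
    """Decode the average of the two images' latents.

    The companion is typically the current mask rendered as a {0,1} image or
    the all-black reference; with two arbitrary images this reproduces the
    latent-blending (reconstruction noise) demonstration.
    """
    if image.shape != companion.shape:
        raise InputError("image and companion must share a shape")
    fa = mix_features(encode(image, weights), encode(companion, weights))
    return decode(fa, weights)


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximising between-class variance over a 256-bin histogram.

    Returns the bin edge separating the two classes; ties resolve to the
    lowest maximising bin.  Raises on constant input.
    """
    flat = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = float(flat.min()), float(flat.max())
    if vmin == vmax:
        raise DegenerateInputError("constant input has no Otsu threshold")
    counts, edges = np.histogram(flat, bins=256, range=(vmin, vmax))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(counts)[:-1]                      # class 0 = bins < k
    w1 = total - w0
    mu0 = np.cumsum(counts * centers)[:-1]
    mu_total = (counts * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = mu0 / w0
        m1 = (mu_total - mu0) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b)) + 1                  # argmax takes lowest tie
    return float(edges[k])


class StepResult(NamedTuple):
    mask: np.ndarray
    threshold: float | None
    degenerate: bool


def _restrict_to_seed_components(mask: np.ndarray,
                                 seed: np.ndarray) -> np.ndarray:
    """Keep only 8-connected components of ``mask`` that intersect ``seed``."""
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return mask
    hit = np.unique(labels[seed & mask])
    hit = hit[hit > 0]
    return np.isin(labels, hit)


def segmentation_step(image: np.ndarray, mask: np.ndarray,
                      weights: AutoencoderWeights,
                      dilation_iterations: int = DEFAULT_DILATION_ITERATIONS,
                      bandwidth: float | str = "auto",
                      restrict_components: bool = True,
                      signed_difference: bool = True) -> StepResult:
    """One growth step from the current mask.

    Computes the density-remapped image x, the two mixed reconstructions
    a(x, mask) and a(x, black), thresholds their difference with Otsu and
    restricts the result to components touching the previous mask.  If the
    difference image is constant the mask is returned unchanged with the
    ``degenerate`` flag set.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("segmentation step requires a non-empty mask")
    x = adjust_intensity(image, mask, iterations=dilation_iterations,
                         bandwidth=bandwidth)
    fx = encode(x, weights)
    f_mask = encode(render_mask(mask), weights)
    a_mask = decode(mix_features(fx, f_mask), weights)
    a_black = decode(mix_features(fx, _black_latent(image.shape, weights)),
                     weights)
    diff = a_mask.astype(np.float64) - a_black.astype(np.float64)
    if signed_difference:
        diff = np.clip(diff, 0.0, None)
    else:
        diff = np.abs(diff)
    try:
        thr = otsu_threshold(diff)
    except DegenerateInputError:
        return StepResult(mask=mask, threshold=None, degenerate=True)
    new_mask = diff >= thr
    if restrict_components:
        new_mask = _restrict_to_seed_components(new_mask, mask)
    if not new_mask.any():
        return StepResult(mask=mask, threshold=thr, degenerate=True)
    return StepResult(mask=new_mask, threshold=thr, degenerate=False)


@dataclass
class SegmentationState:
    """Outcome of one click-seeded growth run."""

    current_mask: np.ndarray
    iteration: int
    history: list[int] = field(default_factory=list)   # mask areas per step
    converged: bool = False
    threshold_trace: list[float | None] = field(default_factory=list)


def run_initial_segmentation(image: np.ndarray, click: Click,
                             weights: AutoencoderWeights,
                             max_iterations: int = DEFAULT_MAX_ITERATIONS,
                             **step_kwargs) -> SegmentationState:
    """Grow the 5-pixel click dot into a segmentation mask.

    Iterates :func:`segmentation_step` until two consecutive masks are
    identical (converged), a previously seen mask recurs (cycle; not
    converged), or ``max_iterations`` is reached.  Fully deterministic for a
    fixed image, click, and weights.
    """
    if not click.positive:
        raise InputError("initial segmentation requires a positive click")
    mask = click_to_dot(click, image.shape)
    seen = {mask.tobytes()}
    state = SegmentationState(current_mask=mask, iteration=0,
                              history=[int(mask.sum())])
    for it in range(1, max_iterations + 1):
        result = segmentation_step(image, mask, weights, **step_kwargs)
        state.threshold_trace.append(result.threshold)
        new_mask = result.mask
        state.iteration = it
        state.history.append(int(new_mask.sum()))
        if np.array_equal(new_mask, mask):
            state.current_mask = mask
            state.converged = True
            return state
        key = new_mask.tobytes()
        if key in seen:
            state.current_mask = new_mask
            state.converged = False   # oscillation detected
            return state
        seen.add(key)
        mask = new_mask
        state.current_mask = mask
    return state
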