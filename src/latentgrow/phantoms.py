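"""Synthetic CT-like phantoms with ground-truth masks, and a texture corpus.

Phantoms are piecewise-smooth images: organ-like blobs (ellipses perturbed by
a low-order Fourier series in the radius, so boundaries are smooth but not
circular) with distinct per-organ intensity distributions, plus Gaussian
pixel noise.  Organ mean intensities are separated by several times the noise
level so the density-based remap is well-posed — the regime the soft-tissue
CT window produces on real slices.

The background emulates what a windowed abdominal CT slice looks like outside
the target organ: not one uniform tissue but a heterogeneous mix — a dark
textured base plus several "distractor" structures at varied intensities with
broader internal spread than the target organs.  This heterogeneity matters:
the density remap assumes the clicked organ is the dominant intensity mode of
its surroundings, which holds on real slices precisely because the
surroundings are mixed.  Distractor structures carry no ground-truth masks.

The texture corpus mixes phantoms with gradients, blob fields and filtered
noise; it exists to train the reduced-width fixture autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError


class GenerationError(RuntimeError):
    """Phantom configuration cannot be realised (organs do not fit)."""


@dataclass(frozen=True)
class OrganSpec:
    mean: float
    std: float = 0.03
    radius_frac: tuple[float, float] = (0.12, 0.20)  # of min(H, W)


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int] = (256, 256)
    organs: tuple[OrganSpec, ...] = (OrganSpec(0.70), OrganSpec(0.45),
                                     OrganSpec(0.30))
    background_mean: float = 0.02   # air-like: mostly clips to exactly 0
    noise_std: float = 0.02
    max_harmonics: int = 5
    min_organ_pixels: int = 50
    separation_pixels: int = 6     # dilation gap enforced between organs
    n_distractors: int = 4         # non-target background structures
    distractor_means: tuple[float, float] = (0.2, 0.9)
    distractor_std: float = 0.06   # broader than organ std: fuzzier tissue

    def __post_init__(self):
        if len(self.organs) < 1:
            raise InputError("config needs at least one organ")


@dataclass
class PhantomSample:
    image: np.ndarray
    organ_masks: dict[str, np.ndarray]
    config: PhantomConfig
    seed: int


def _blob_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float, rng: np.random.Generator,
               max_harmonics: int) -> np.ndarray:
    """Rasterise a Fourier-perturbed ellipse-like blob."""
    h, w = shape
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    theta = np.arctan2(rows, cols)
    dist = np.hypot(rows, cols)
    r_theta = np.full_like(theta, radius)
    n_harm = int(rng.integers(2, max_harmonics + 1))
    for k in range(1, n_harm + 1):
        amp = rng.uniform(0.0, 0.15 / k) * radius
        phase = rng.uniform(0, 2 * np.pi)
        r_theta = r_theta + amp * np.cos(k * theta + phase)
    return dist <= r_theta


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float, scale: float) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma)
    sd = sm.std()
    return sm / sd * scale if sd > 0 else sm


def generate_phantom(config: PhantomConfig | None = None,
                     seed: int = 0) -> PhantomSample:
    """Render a phantom with pairwise-disjoint organ masks; pure in (config, seed)."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    h, w = config.shape
    occupied = np.zeros((h, w), dtype=bool)
    masks: dict[str, np.ndarray] = {}
    sep = np.ones((3, 3), dtype=bool)
    for i, organ in enumerate(config.organs):
        placed = False
        for _ in range(200):
            radius = rng.uniform(*organ.radius_frac) * min(h, w)
            margin = radius * 1.2
            if 2 * margin >= min(h, w):
                continue
            center = (rng.uniform(margin, h - margin),
                      rng.uniform(margin, w - margin))
            mask = _blob_mask((h, w), center, radius, rng,
                              config.max_harmonics)
            if mask.sum() < config.min_organ_pixels:
                continue
            grown = ndimage.binary_dilation(
                mask, structure=sep, iterations=config.separation_pixels)
            if (grown & occupied).any():
                continue
            occupied |= grown
            masks[f"organ_{i}"] = mask
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place organ {i} after 200 attempts")

    # Air-like base: most of it clips to exactly 0, as sub-window CT values do
    # after windowing; zero pixels are excluded from the density fit.
    image = config.background_mean + _smooth_noise((h, w), rng, sigma=8.0,
                                                   scale=0.03)
    # Distractor tissue: varied intensities, no ground truth.  Kept spatially
    # apart from the targets and away from their intensity modes — an organ
    # directly abutting same-intensity tissue is the method's documented
    # failure mode, not the baseline scenario the phantom emulates.
    organ_means = [o.mean for o in config.organs]
    for _ in range(config.n_distractors):
        for _attempt in range(50):
            mean = float(rng.uniform(*config.distractor_means))
            if min(abs(mean - m) for m in organ_means) < 0.15:
                continue
            radius = rng.uniform(0.08, 0.18) * min(h, w)
            center = (rng.uniform(0, h), rng.uniform(0, w))
            blob = _blob_mask((h, w), center, radius, rng,
                              config.max_harmonics)
            grown = ndimage.binary_dilation(
                blob, structure=sep, iterations=config.separation_pixels)
            if (grown & occupied).any():
                continue
            tissue = mean + rng.normal(0.0, config.distractor_std,
                                       size=(h, w))
            image = np.where(blob, tissue, image)
            break
    for i, organ in enumerate(config.organs):
        mask = masks[f"organ_{i}"]
        tissue = organ.mean + rng.normal(0.0, organ.std, size=(h, w))
        image = np.where(mask, tissue, image)
    image = image + rng.normal(0.0, config.noise_std, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(image=image, organ_masks=masks, config=config,
                         seed=seed)


def single_organ_config(shape: tuple[int, int] = (128, 128),
                        mean: float = 0.70) -> PhantomConfig:
    """One bright organ on a dark background — the basic recovery scenario."""
    return PhantomConfig(shape=shape, organs=(OrganSpec(mean),))


def two_organ_config(shape: tuple[int, int] = (128, 128)) -> PhantomConfig:
    return PhantomConfig(shape=shape, organs=(OrganSpec(0.70),
                                              OrganSpec(0.45)))


def generate_texture_corpus(n: int, size: tuple[int, int] = (128, 128),
                            seed: int = 0) -> list[np.ndarray]:
    """Diverse training images: phantoms, gradients, blob fields, noise."""
    if n < 1:
        raise InputError("corpus size must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = size
    images: list[np.ndarray] = []
    rows = np.linspace(0, 1, h)[:, None]
    cols = np.linspace(0, 1, w)[None, :]
    for i in range(n):
        kind = i % 3
        sub = int(rng.integers(0, 2 ** 31 - 1))
        if kind == 0:
            n_organs = int(rng.integers(1, 4))
            means = rng.uniform(0.25, 0.85, size=n_organs)
            cfg = PhantomConfig(shape=size,
                                organs=tuple(OrganSpec(float(m))
                                             for m in means),
                                background_mean=float(rng.uniform(0.05, 0.2)))
            try:
                images.append(generate_phantom(cfg, seed=sub).image)
            except GenerationError:
                images.append(np.clip(
                    _smooth_noise(size, rng, 8.0, 0.2) + 0.5, 0, 1))
        elif kind == 1:
            a, b = rng.uniform(-1, 1, size=2)
            grad = 0.5 + 0.45 * (a * (rows - 0.5) + b * (cols - 0.5)) * 2
            grad = grad + _smooth_noise(size, rng, 4.0, 0.08)
            images.append(np.clip(grad, 0.0, 1.0))
        else:
            sigma = float(rng.uniform(1.0, 10.0))
            tex = 0.5 + _smooth_noise(size, rng, sigma, 0.25)
            images.append(np.clip(tex, 0.0, 1.0))
    return images
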