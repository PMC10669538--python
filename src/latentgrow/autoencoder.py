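"""VGG19-style convolutional autoencoder used for latent feature mixing.

The encoder is the convolutional part of VGG19 truncated after the first
convolution of the deepest configured block (default: 3 of the 5 blocks, so
the latent is the relu3_1 activation grid).  The decoder mirrors the encoder
with the channel sequence reversed and each max-pool replaced by a
nearest-neighbour 2x upsample.  All 3x3 convolutions use reflection padding 1
so spatial size is preserved; with two pooling steps the latent of an H x W
image is C x ceil(H/4) x ceil(W/4).

Grayscale images are replicated to three channels at the encoder input and
reduced back by channel averaging (after clamping to [0, 1]) at the decoder
output.  The decoder ends in a mirrored 3x3 projection to three channels and
a 1x1 projection without ReLU.

A small "fixture" variant with the identical topology but reduced channel
widths can be trained on a synthetic texture corpus in minutes on one CPU;
externally trained full-width weights are a drop-in via ``load_weights``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigurationError, InputError

# VGG19 convolutional plan: convs per block and output channels per block.
_VGG19_CONVS_PER_BLOCK = (2, 2, 4, 4, 4)
_VGG19_CHANNELS = (64, 128, 256, 512, 512)


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture description: depth and (optionally reduced) widths.

    ``depth_blocks`` counts VGG19 convolutional blocks; the encoder keeps the
    full blocks 1..depth-1 (each followed by a 2x2 max pool) plus the first
    convolution of block ``depth``.  ``width_divisor`` divides every channel
    width, keeping the topology; 1 reproduces the reference architecture
    exactly.
    """

    depth_blocks: int = 3
    width_divisor: int = 1

    def __post_init__(self):
        if self.depth_blocks not in (1, 2, 3, 4, 5):
            raise ConfigurationError("depth_blocks must be in 1..5")
        if self.width_divisor < 1:
            raise ConfigurationError("width_divisor must be >= 1")

    def _width(self, block: int) -> int:
        return max(2, _VGG19_CHANNELS[block - 1] // self.width_divisor)

    @property
    def latent_channels(self) -> int:
        return self._width(self.depth_blocks)

    @property
    def n_pools(self) -> int:
        return self.depth_blocks - 1

    def encoder_layers(self) -> list[tuple]:
        """Ordered (name, kind, c_in, c_out, kernel) descriptors."""
        layers: list[tuple] = [("enc_conv0", "conv", 3, 3, 1)]
        c_prev = 3
        for b in range(1, self.depth_blocks + 1):
            c = self._width(b)
            n_convs = 1 if b == self.depth_blocks else _VGG19_CONVS_PER_BLOCK[b - 1]
            for i in range(1, n_convs + 1):
                layers.append((f"enc_conv{b}_{i}", "conv", c_prev, c, 3))
                c_prev = c
            if b < self.depth_blocks:
                layers.append((f"enc_pool{b}", "pool", c, c, 2))
        return layers

    def decoder_layers(self) -> list[tuple]:
        """Mirror of the encoder: reversed convs, pools become upsamples."""
        out: list[tuple] = []
        for name, kind, c_in, c_out, k in reversed(self.encoder_layers()):
            dname = name.replace("enc_", "dec_").replace("pool", "up")
            if kind == "pool":
                out.append((dname, "up", c_in, c_out, 2))
            else:
                out.append((dname, "conv", c_out, c_in, k))
        return out

    def to_dict(self) -> dict:
        return {"depth_blocks": self.depth_blocks,
                "width_divisor": self.width_divisor}

    @classmethod
    def from_dict(cls, d: dict) -> "AutoencoderSpec":
        return cls(depth_blocks=int(d["depth_blocks"]),
                   width_divisor=int(d.get("width_divisor", 1)))


# Fixture configuration: identical topology, widths 8/16/32, trainable on CPU.
FIXTURE_SPEC = AutoencoderSpec(depth_blocks=3, width_divisor=8)


@dataclass
class LatentFeature:
    """Deepest-block activation grid of one image."""

    values: np.ndarray          # (C, h, w) float32
    source_shape: tuple[int, int]

    def __post_init__(self):
        if self.values.ndim != 3:
            raise InputError("latent must be a C x h x w grid")
        if not np.all(np.isfinite(self.values)):
            raise InputError("latent contains non-finite values")


def _build_layers(descs: list[tuple], final_no_relu: bool = False):
    layers = []
    for i, (name, kind, c_in, c_out, k) in enumerate(descs):
        if kind == "conv":
            relu = not (final_no_relu and i == len(descs) - 1)
            layers.append(_nn.Conv2d(name, c_in, c_out, k, relu=relu))
        elif kind == "pool":
            layers.append(_nn.MaxPool2())
        else:
            layers.append(_nn.NearestUp2())
    return layers


class AutoencoderWeights:
    """Bound parameters for one :class:`AutoencoderSpec`.

    Holds the live layer objects for both halves; ``history`` records the
    fixture-training loss curve when the weights were trained in-process.
    """

    def __init__(self, spec: AutoencoderSpec, seed: int | None = None):
        self.spec = spec
        self.encoder = _build_layers(spec.encoder_layers())
        self.decoder = _build_layers(spec.decoder_layers(), final_no_relu=True)
        self.history: dict[str, list[float]] = {}
        if seed is not None:
            rng = np.random.default_rng(seed)
            for layer in self.encoder + self.decoder:
                if isinstance(layer, _nn.Conv2d):
                    layer.init_params(rng)

    def _conv_layers(self):
        for layer in self.encoder + self.decoder:
            if isinstance(layer, _nn.Conv2d):
                yield layer

    def param_count(self) -> int:
        return sum(l.W.size + l.b.size for l in self._conv_layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self._conv_layers():
            out[f"{l.name}.W"] = l.W
            out[f"{l.name}.b"] = l.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        expected = {f"{l.name}.{s}" for l in self._conv_layers()
                    for s in ("W", "b")}
        unexpected = sorted(set(state) - expected)
        if unexpected:
            raise ConfigurationError(
                f"layer {unexpected[0].rsplit('.', 1)[0]} not part of this "
                f"architecture (depth/width mismatch?)")
        for l in self._conv_layers():
            for suffix, expected in (("W", l.W.shape), ("b", l.b.shape)):
                key = f"{l.name}.{suffix}"
                if key not in state:
                    raise ConfigurationError(f"missing weights for layer {l.name}")
                arr = np.asarray(state[key], dtype=_nn.DTYPE)
                if arr.shape != expected:
                    raise ConfigurationError(
                        f"layer {l.name}: expected {suffix} shape {expected}, "
                        f"got {arr.shape}")
            l.W = np.asarray(state[f"{l.name}.W"], dtype=_nn.DTYPE)
            l.b = np.asarray(state[f"{l.name}.b"], dtype=_nn.DTYPE)


def _to_3ch(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=_nn.DTYPE)
    if img.ndim != 2:
        raise InputError("expected a 2-D grayscale image")
    return np.repeat(img[None, None], 3, axis=1)


def encode(image: np.ndarray, weights: AutoencoderWeights) -> LatentFeature:
    """Activation grid after the deepest configured encoder block."""
    if np.nanmin(image) < -1e-6 or np.nanmax(image) > 1 + 1e-6:
        raise InputError("image values must lie in [0, 1]")
    x = _to_3ch(image)
    y = _nn.forward_layers(weights.encoder, x)
    return LatentFeature(values=y[0], source_shape=image.shape)


def _pool_stage_shapes(shape: tuple[int, int], n_pools: int):
    """Spatial sizes before each pooling step, outermost first."""
    shapes = [shape]
    h, w = shape
    for _ in range(n_pools):
        h, w = -(-h // 2), -(-w // 2)
        shapes.append((h, w))
    return shapes


def decode(latent: LatentFeature, weights: AutoencoderWeights) -> np.ndarray:
    """Reconstruct an H x W image in [0, 1] from a latent feature."""
    c = latent.values.shape[0]
    if c != weights.spec.latent_channels:
        raise ConfigurationError(
            f"latent has {c} channels, decoder expects "
            f"{weights.spec.latent_channels}")
    stages = _pool_stage_shapes(latent.source_shape, weights.spec.n_pools)
    # Upsamples restore, in order, the sizes the pools consumed (deepest first).
    targets = list(reversed(stages[:-1]))
    ups = [l for l in weights.decoder if isinstance(l, _nn.NearestUp2)]
    for up, hw in zip(ups, targets):
        up.target_hw = hw
    y = _nn.forward_layers(weights.decoder, latent.values[None])
    img = np.clip(y[0], 0.0, 1.0).mean(axis=0)
    return img


def reconstruct(image: np.ndarray, weights: AutoencoderWeights) -> np.ndarray:
    return decode(encode(image, weights), weights)


def train_fixture_autoencoder(
    corpus: list[np.ndarray],
    epochs: int = 12,
    seed: int = 0,
    spec: AutoencoderSpec = FIXTURE_SPEC,
    lr: float = 2e-3,
    batch_size: int = 8,
    latent_noise: float = 0.5,
    eval_corpus: list[np.ndarray] | None = None,
) -> AutoencoderWeights:
    """Train a reduced-width autoencoder on a texture corpus.

    Minimises pixel MSE between input and (unclamped) decoder output with
    Adam.  During training, Gaussian noise scaled by ``latent_noise`` times
    the latent's standard deviation is injected at the bottleneck: the
    decoder learns to reconstruct through a corrupted code, which gives the
    trained model the deliberately imperfect, smearing reconstructions
    (reconstruction noise) that the mask-growth mechanism feeds on — the
    counterpart of decoding through features that were never optimised for
    reconstruction.  Fully reproducible for a fixed seed; intended for small
    corpora (hundreds of images at <= 128 x 128), minutes on one CPU.
    """
    if not corpus:
        raise InputError("training corpus is empty")
    shapes = {im.shape for im in corpus}
    if len(shapes) != 1:
        raise InputError("corpus images must share one size")
    weights = AutoencoderWeights(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    data = np.stack([np.asarray(im, dtype=_nn.DTYPE) for im in corpus])
    data = np.repeat(data[:, None], 3, axis=1)
    opt = _nn.Adam(weights.encoder + weights.decoder, lr=lr)
    n = data.shape[0]
    train_losses, eval_losses = [], []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = data[order[start:start + batch_size]]
            z = _nn.forward_layers(weights.encoder, batch, train=True)
            if latent_noise:
                z = z + (latent_noise * z.std() *
                         rng.standard_normal(z.shape)).astype(_nn.DTYPE)
            y = _nn.forward_layers(weights.decoder, z, train=True)
            diff = (y - batch).astype(_nn.DTYPE)
            epoch_loss += float(np.mean(diff ** 2)) * batch.shape[0]
            dy = (2.0 / diff.size) * diff
            dz = _nn.backward_layers(weights.decoder, dy)
            _nn.backward_layers(weights.encoder, dz)
            opt.step()
        train_losses.append(epoch_loss / n)
        if eval_corpus is not None:
            errs = [float(np.mean((reconstruct(im, weights) - im) ** 2))
                    for im in eval_corpus]
            eval_losses.append(float(np.mean(errs)))
    weights.history = {"train_loss": train_losses}
    if eval_corpus is not None:
        weights.history["eval_loss"] = eval_losses
    return weights


def save_weights(weights: AutoencoderWeights, path: str | Path) -> None:
    """Write weights as a .npz archive with a JSON spec sidecar."""
    path = Path(path)
    np.savez(path, **weights.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(weights.spec.to_dict()))


def load_weights(path: str | Path,
                 spec: AutoencoderSpec | None = None) -> AutoencoderWeights:
    """Load weights saved by :func:`save_weights`, validating layer shapes."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"weights file not found: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if spec is None:
        if not sidecar.exists():
            raise ConfigurationError(f"missing spec sidecar: {sidecar}")
        spec = AutoencoderSpec.from_dict(json.loads(sidecar.read_text()))
    weights = AutoencoderWeights(spec)
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    weights.load_state_dict(state)
    return weights
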