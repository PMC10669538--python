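"""Simulated-click evaluation: Dice scores and interactive sessions.

The click simulator mimics an annotator correcting the largest error: it
finds the biggest connected component of false negatives or false positives
and clicks its interior-most pixel (distance-transform argmax; lowest row,
then column on ties).  A session starts from one positive click, grows an
initial mask, then alternates simulated corrective clicks with refinement,
recording the Dice score after every click; the best-Dice-per-click curve is
the running maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .autoencoder import AutoencoderWeights
from .diffusion_core import run_initial_segmentation
from .errors import InputError
from .preprocess import Click
from .refinement import apply_negative_click, apply_positive_click

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _largest_component(mask: np.ndarray) -> np.ndarray | None:
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def interior_most_pixel(region: np.ndarray,
                        rng: np.random.Generator | None = None,
                        jitter: bool = False) -> tuple[int, int]:
    """Pixel of the region farthest from its boundary.

    Deterministic argmax of the Euclidean distance transform (first pixel in
    row-major order on ties); with ``jitter`` a uniformly random pixel among
    those at least half the maximal depth is drawn from ``rng``.
    """
    dist = ndimage.distance_transform_edt(region)
    if jitter:
        if rng is None:
            raise InputError("jitter requires an rng")
        candidates = np.argwhere(dist >= dist.max() / 2)
        r, c = candidates[rng.integers(len(candidates))]
        return int(r), int(c)
    idx = int(np.argmax(dist))
    return int(idx // region.shape[1]), int(idx % region.shape[1])


def simulate_next_click(pred: np.ndarray, truth: np.ndarray,
                        rng: np.random.Generator | None = None,
                        jitter: bool = False) -> Click | None:
    """Corrective click targeting the largest error component.

    The bigger of the largest false-negative component (positive click) and
    the largest false-positive component (negative click) wins; the click
    lands on its interior-most pixel.  Returns ``None`` when prediction and
    truth agree exactly (session complete).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth must share a shape")
    if not truth.any():
        raise InputError("truth mask is empty")
    fn = _largest_component(truth & ~pred)
    fp = _largest_component(pred & ~truth)
    if fn is None and fp is None:
        return None
    if fp is None or (fn is not None and fn.sum() >= fp.sum()):
        region, positive = fn, True
    else:
        region, positive = fp, False
    r, c = interior_most_pixel(region, rng=rng, jitter=jitter)
    return Click(r, c, positive)


@dataclass
class SessionRecord:
    """Per-click history of one simulated interactive session."""

    clicks: list[Click] = field(default_factory=list)
    dice_per_click: list[float] = field(default_factory=list)
    seed: int = 0
    masks: list[np.ndarray] | None = None

    @property
    def best_dice_per_click(self) -> list[float]:
        return list(np.maximum.accumulate(self.dice_per_click)) \
            if self.dice_per_click else []

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "clicks": [[int(c.row), int(c.col), bool(c.positive)]
                       for c in self.clicks],
            "dice_per_click": [float(d) for d in self.dice_per_click],
            "best_dice_per_click": [float(d) for d in self.best_dice_per_click],
        })

    @classmethod
    def from_json(cls, text: str) -> "SessionRecord":
        d = json.loads(text)
        rec = cls(seed=int(d.get("seed", 0)))
        rec.clicks = [Click(int(r), int(c), bool(p))
                      for r, c, p in d["clicks"]]
        rec.dice_per_click = [float(x) for x in d["dice_per_click"]]
        return rec

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SessionRecord":
        return cls.from_json(Path(path).read_text())


def _run_clicks(image: np.ndarray, clicks: list[Click],
                weights: AutoencoderWeights, store_masks: bool,
                **segmentation_kwargs) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply a click sequence: initial growth, then refinement in order."""
    if not clicks or not clicks[0].positive:
        raise InputError("a session starts with a positive click")
    mask = run_initial_segmentation(image, clicks[0], weights,
                                    **segmentation_kwargs).current_mask
    masks = [mask]
    positives = [clicks[0]]
    for click in clicks[1:]:
        if click.positive:
            mask = apply_positive_click(image, mask, click, weights,
                                        **segmentation_kwargs)
            positives.append(click)
        else:
            mask, _ = apply_negative_click(mask, positives, click)
        masks.append(mask)
    return mask, masks if store_masks else [mask]


def interactive_session(image: np.ndarray, truth: np.ndarray,
                        weights: AutoencoderWeights, max_clicks: int = 5,
                        seed: int = 0, jitter: bool = False,
                        store_masks: bool = False,
                        **segmentation_kwargs) -> SessionRecord:
    """Simulate an interactive session against a ground-truth mask.

    The first (positive) click is the interior-most pixel of the truth; each
    later click corrects the largest remaining error.  Dice is recorded after
    every click.  Deterministic for a fixed seed.
    """
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise InputError("truth mask is empty")
    if max_clicks < 1:
        raise InputError("max_clicks must be >= 1")
    rng = np.random.default_rng(seed)
    record = SessionRecord(seed=seed, masks=[] if store_masks else None)

    first = simulate_next_click(np.zeros_like(truth), truth,
                                rng=rng, jitter=jitter)
    mask = run_initial_segmentation(image, first, weights,
                                    **segmentation_kwargs).current_mask
    positives = [first]
    record.clicks.append(first)
    record.dice_per_click.append(dice(mask, truth))
    if store_masks:
        record.masks.append(mask)

    while len(record.clicks) < max_clicks:
        click = simulate_next_click(mask, truth, rng=rng, jitter=jitter)
        if click is None:
            break
        if click.positive:
            mask = apply_positive_click(image, mask, click, weights,
                                        **segmentation_kwargs)
            positives.append(click)
        else:
            mask, _ = apply_negative_click(mask, positives, click)
        record.clicks.append(click)
        record.dice_per_click.append(dice(mask, truth))
        if store_masks:
            record.masks.append(mask)
    return record


def replay_session(image: np.ndarray, truth: np.ndarray,
                   record: SessionRecord, weights: AutoencoderWeights,
                   **segmentation_kwargs) -> list[float]:
    """Re-apply a stored click sequence and return the per-click Dice values."""
    _, masks = _run_clicks(image, record.clicks, weights, store_masks=True,
                           **segmentation_kwargs)
    return [dice(m, truth) for m in masks]
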