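# latentgrow

Training-free interactive segmentation of 2-D medical images (CT/MRI slices)
from single clicks, for researchers who need organ masks without any
segmentation ground truth or task-specific training.

A click is turned into a 5-pixel seed mask g₀ and grown into a segmentation
by a fixed-point iteration.  Each step:

1. remaps the image I by the kernel density of pixel values around the
   current mask gₜ — x = kde(crop(I, gₜ))(I), normalised to peak at 1 — so the
   clicked organ becomes a bright soft indicator;
2. blends x with the rendered mask in the latent space of a VGG19-style
   convolutional autoencoder, a(x, gₜ) = D((E(x) + E(gₜ))/2), and likewise
   with an all-black reference o;
3. binarises d = max(a(x, gₜ) − a(x, o), 0) with Otsu's threshold and keeps
   the connected components touching gₜ, giving gₜ₊₁.

The iteration stops when gₜ₊₁ = gₜ.  The decoder's imperfect reconstruction
("reconstruction noise") makes the seed's influence spread preferentially
within tissue that resembles the clicked organ, so the mask grows to the
organ and largely stops at its boundary.  Further positive clicks grow and
union extra regions; negative clicks remove regions via a Gaussian
density comparison around the clicks.  A simulated annotator (largest error
component, interior-most pixel) scores sessions by Dice per click.

No dataset download is required anywhere: a phantom generator renders
CT-like test images with ground-truth masks, and a small fixture autoencoder
is trained on a synthetic texture corpus in minutes on one CPU.  Externally
trained full-width weights can be dropped in via `load_weights`.

## Worked example

```python
import numpy as np
import latentgrow as lg

# synthetic data stands in for a windowed CT slice + ground truth
corpus = lg.generate_texture_corpus(150, size=(128, 128), seed=0)
weights = lg.train_fixture_autoencoder(corpus, epochs=12, seed=0)

sample = lg.generate_phantom(lg.single_organ_config(), seed=1)
truth = sample.organ_masks["organ_0"]

rr, cc = np.nonzero(truth)
click = lg.Click(int(rr.mean()), int(cc.mean()))          # click the organ
state = lg.run_initial_segmentation(sample.image, click, weights)
print(f"converged={state.converged} after {state.iteration} iterations, "
      f"dice={lg.dice(state.current_mask, truth):.3f}")

record = lg.interactive_session(sample.image, truth, weights,
                                max_clicks=5, seed=0)
print("best dice per click:",
      [f"{d:.2f}" for d in record.best_dice_per_click])
```

Output:

```
converged=False after 37 iterations, dice=0.350
best dice per click: ['0.35', '0.51', '0.60', '0.65', '0.73']
```

The first line is the one-click mask: the seed grew through part of the organ
and then entered a limit cycle (flagged not-converged), covering about a
third of it.  The second line shows the simulated refinement loop closing
much of the remaining gap — the best-Dice curve is non-decreasing by
construction, and each extra click targets the largest remaining error
region.  With the small CPU-trained fixture autoencoder, five clicks
typically reach Dice ≈ 0.7–0.8 on these phantoms (see docs/methods.md for
why the fixture's reconstruction-noise profile bounds this, and how stronger
pretrained weights slot in).

The same flow is available from a shell:

```bash
latentgrow train-fixture --out weights.npz --seed 0
latentgrow phantom --out-dir ph --seed 1 --size 128 --organs 1
latentgrow segment ph/image.png 64,64 --weights weights.npz --out mask.png
latentgrow evaluate ph/image.png ph/organ_0.png --weights weights.npz \
    --out session.json --max-clicks 5
```

For real data, `segment` reads PNG or NIfTI (with `--slice-index`), windows
CT at [−135, 215] and MRI at [100, 1000] by default, and works in 0-based
(row, col) pixel coordinates throughout.

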