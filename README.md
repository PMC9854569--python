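# spcnet

Star-convex polygon instance segmentation for adherent, circular-like cells in
single-channel microscopy images.

A cell is represented as a star polygon: a center plus radial distances along
32 equiangular rays. Instance label maps are encoded into two dense training
targets — a per-pixel object probability (normalized Euclidean distance to the
nearest background pixel) and a 32-channel radial-distance map — which a
U-shaped attention network regresses jointly. At inference, every
high-probability pixel proposes its polygon, and polygon-based adaptive
non-maximum suppression (PA-NMS) keeps one polygon per cell: the suppression
IoU threshold for the current best proposal M is raised from the base `Nt` to
`max(Nt, d_M)`, where `d_M` measures how crowded M's neighborhood is, so
adherent cells survive while duplicates are removed.

The network (an encoder-decoder with residual attention-embedding encoder
blocks, an optional ASPP bottleneck, and two point-wise heads) and its
training loop run on a small numpy reverse-mode autodiff engine bundled in
`spcnet.nn` — no deep-learning framework is required. Every op is
gradient-checked against finite differences in the test suite.

## Layout

| Module | Role |
| --- | --- |
| `spcnet.geometry` | star polygons: rays, vertices, area, IoU, rasterization |
| `spcnet.codec` | label map -> (probability, radial distance) targets and back |
| `spcnet.nn` | numpy autodiff: conv2d, pooling, bilinear upsampling, SGD |
| `spcnet.network` | the segmentation network and its ablation variants |
| `spcnet.training` | Eq.-style joint loss (BCE + weighted MAE), augmentation, training loop |
| `spcnet.postprocess` | proposal extraction, detection density, PA-NMS, full inference |
| `spcnet.metrics` | Dice, pixel TP/FP rates, object FN rate, AP at IoU threshold tau |
| `spcnet.synth` | seeded generator of adherent-cell images with instance ground truth |
| `spcnet.cli` | `spcnet generate / train / predict / evaluate / ablate` |

## CLI

```sh
# 200 synthetic 256x256 adherent-cell images with instance label maps
spcnet generate --n 200 --seed 1 --out data/

# train (defaults: SGD momentum 0.99, weight decay 1e-8, lr 1e-3, batch 12,
# 650 epochs, 8:2 split; scale down with flags)
spcnet train --data data/ --out runs/demo --epochs 30 --base-channels 8

# segment one image: label TIFF + proposal CSV + overlay PNG
spcnet predict --weights runs/demo/train_weights.npz --image data/img_0000.tif --out preds/

# pixel + object metrics (percentages, 2 decimals)
spcnet evaluate --pred preds/img_0000_labels.tif --gt data/lbl_0000.tif

# scaled-down ablation table: 4 encoder variants, +/-ASPP, NMS vs PA-NMS
spcnet ablate --data data/ --out runs/ablation --epochs 5
```

Config files are YAML with `generator:`, `network:`, `train:` sections mirroring
the dataclass fields (`GeneratorConfig`, `NetworkConfig`, `TrainConfig`).

## Acceptance

The acceptance properties (codec round-trip fidelity, geometry/NMS oracles,
loss identities, scaled-down learning, metric identities, ablation harness)
run as `tests/test_acceptance.py`. The report script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

exercises the full pipeline end-to-end at small scale and writes the report
JSON (empty: no numeric acceptance targets are defined for this build).

## Notes

- Label maps are 16-bit single-channel TIFFs (0 = background, k = cell k);
  images are PNG or TIFF grayscale.
- `PostprocessConfig.density` selects how detection density is estimated:
  `"object"` (default; crowding by other objects, robust with per-pixel
  proposals) or `"pairwise"` (max IoU against any other proposal).
- Training is deterministic for a fixed seed on fixed hardware.
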