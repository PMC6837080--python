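# rowgraphics

Crop-row and plant-base detection for paddy fields, trained from *graphic*
annotations instead of dense per-pixel labels: thin polylines mark crop rows
and depth-scaled discs mark plant bases (crop vs. grass-weed). The package
contains

- **`synthetic_scene`** — a seeded generator of paddy-field-like scenes
  (perspective-converging rows of plant blobs, inter-row weeds) with exact
  ground-truth graphics, so the full pipeline is testable end to end;
- **`annotation`** — the graphic-annotation data model, rasterization to
  integer label masks, inverse-frequency class weights, JSON/PNG I/O;
- **`network`** — a configurable fully-convolutional encoder–decoder with
  *extended skip connections*: each skip combines a channel-preserving 1×1
  path with a bank of learned multi-scale separable large-kernel filters
  contributing 12 extra channels (plus `none` / `fixed` / `single_scale`
  ablation modes), and separable large-kernel blocks at the encoder tail;
- **`training`** — class-weighted pixel-wise cross-entropy, paired
  image/mask augmentation (scale, rotation, mirror, photometric jitter,
  random crop), stepwise exponential learning-rate decay, Adam, Xavier
  initialization;
- **`line_extraction`** — a consensus-style dominant-line extractor: seed on
  the longest connected segment, fit `col = a·row + b`, collect inliers
  within a horizontal threshold, refit once, then suppress explained
  segments and repeat;
- **`evaluation`** — pooled per-class IoU / mIoU, distance-thresholded
  keypoint precision/recall/F1 (greedy one-to-one matching), and mean pixel
  deviation (mpd) between extracted and ground-truth lines;
- **`nn`** — the small numpy reverse-mode autodiff core (im2col
  convolutions, batch norm, pooling, Adam) that backs the network, so the
  package has no deep-learning framework dependency.

## CLI

All stages are exposed through one entry point driven by a YAML run config
(see `tests/test_cli.py` for a complete config example):

```sh
rowgraphics simulate      --config run.yaml --n 50 --out data/        # scenes + manifest
rowgraphics train         --config run.yaml --data data/manifest.tsv --out run/
rowgraphics predict       --checkpoint run/model.ckpt.npz --data data/manifest.tsv --out pred/
rowgraphics extract-lines --mask pred/pred_0000.png --n-lines 4 --out lines.json --overlay overlay.png
rowgraphics evaluate      --checkpoint run/model.ckpt.npz --data data/manifest.tsv --task lines --out report.json
```

Every run writes a resolved config copy and a line-oriented JSON log next to
its outputs; all randomness flows from the single `seed` in the config.

## Notes

- Images are 8-bit RGB PNG; annotations are JSON (`polylines` as
  `[row, col]` point lists, `keypoints` as `{class, center, radius}`);
  masks are single-channel PNG with the class index as pixel value.
- Coordinates are 0-based `(row, col)` with the origin at the top-left.
- Class indices: background = 0 everywhere; `line` = 1 for the row task;
  `paddy` = 1, `millet` = 2 for the keypoint task.
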