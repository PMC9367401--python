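# snakeshot

Contour-based instance segmentation of wild animals with a few-shot
detector: a two-stage pipeline for the common camera-trap situation where
most species have abundant labelled images but some (rare or newly
observed) species have only a handful.

**Stage 1 — few-shot object detection.** A two-stage detector (backbone →
region proposal network → ROI pooling → FC → box classifier + box
regressor) is *base-trained* on the data-rich classes, then *fine-tuned*
for the data-poor ("novel") classes: the feature extractor is frozen and
only the box predictor is retrained on a balanced subset with exactly *n*
images per class (*n*-shot). Classes are split base:novel at 3:1.

**Stage 2 — contour approximation (deep snake).** Each detected box seeds a
contour: the box collapses to the diamond through its edge midpoints; a
circular-convolution snake block predicts the object's four extreme points
from 40 points sampled on the diamond; the extreme points define an octagon
(±¼-edge extension along each box edge, clipped at the corners); the
octagon, sampled at N = 128 vertices, is deformed by a second snake block
over 3 iterations, each round regressing N per-vertex offsets

    out[i] = Σⱼ K[j] · f[(i + j − (k−1)/2) mod N]

— a *circular* convolution, because a contour is a cycle graph. Per-vertex
features are bilinear samples of a convolutional feature grid plus
centroid-relative coordinates.

Quality is scored with IoU = |GT ∩ pred| / |GT ∪ pred| and COCO-style
AP / AP50 / AP75 (thresholds 0.50:0.05:0.95, 101-point interpolation), in
box and mask mode.

Everything — the networks, the autodiff underneath them, the COCO-style
evaluator, and a seeded synthetic camera-trap scene generator with
occlusion / camouflage / truncation / small-target regimes — runs on plain
numpy on one CPU in minutes. See `docs/methods.md` for the model details
and design choices.

## Worked example

Generate a synthetic dataset, train the contour deformer on ground-truth
boxes, segment the evaluation split, and score it:

```bash
snakeshot generate-data --workdir runs --out data/
snakeshot train-snake   --workdir runs --data data/ --out snake.pkl
snakeshot segment       --workdir runs --data data/ --snake snake.pkl \
                        --oracle-boxes --out results.json
snakeshot evaluate      --workdir runs --data data/ --results results.json --mode mask
```

With the default configuration (12 classes × 40 images at 128×128, seed 0)
`train-snake` logs the held-out evaluation

```
held-out mean mask IoU 0.842
```

meaning the deformed 128-vertex contours overlap the ground-truth polygons
at 84 % intersection-over-union on images never seen in training, with the
median IoU rising across the three deformation rounds (0.861 → 0.892 →
0.904) — the iterations refine the contour rather than drift.

The n-shot study (fine-tune at each shot level, evaluate novel and base
classes separately):

```bash
snakeshot nshot-study --workdir runs --data data/ --seeds 0,1,2
```

prints a table whose novel-class AP50 column rises with the shot count;
over seeds {0,1,2} on a 96×96 dataset the means are

```
shots:      1     2     3     5    10    30
novel AP50: 29.8  32.1  31.9  36.3  36.7  43.9
```

i.e. a detector that has seen 30 images of a novel species scores ~1.5x
the AP50 it gets from a single image, while base-class accuracy stays
stable — the signature of feature transfer from base training.

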