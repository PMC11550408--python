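# msanet

Multi-scale heatmap regression for counting and localizing seeds on images
of individual plants, plus a kernel-density vertical seed-distribution
trait for comparing plant genotypes.

## Who this is for

Plant phenotyping groups that point-annotate seed (or pod/organ) centroids
on single-plant crops and want, per plant: a seed count, sub-pixel seed
coordinates, detection quality metrics, and a one-curve summary of where
along the stem the seeds sit — a proxy for shoot architecture that can be
compared across genotypes.

## Method

Sparse point annotations `P = {(x_i, y_i)}` become a dense target: each
point is rasterized to a 1-valued pixel, dilated with a disk structuring
element `B`

    H_d(x, y) = max_{(a,b) ∈ B} H(x + a, y + b),

then smoothed with a normalized Gaussian `G_σ` and peak-normalized so an
isolated seed center equals exactly 1.0.  The label is max-pooled to 1/4,
1/8, 1/16, and 1/32 resolution; because only the plant carries label mass,
the coarse maps act as attention supervision over the whole foreground
plant.

An encoder–decoder predicts at every scale.  Each stage has a sigmoid
head; decoding upsamples each stage's prediction ×2 (nearest neighbor) and
concatenates it with the next shallower stage's features; a final head
emits the full-resolution map `P`.  The loss is

    L = MSE(GT, P) + λ · Σ_{s ∈ S} MSE(GT^s, P^s),   λ = 1,

trained with batch size one at native resolution.  Discrete points are
read out as thresholded local maxima with greedy minimum-distance
suppression.  Evaluation uses one-to-one greedy matching within a pixel
threshold (TP/FP/FN, precision/recall/F1, mean Euclidean distance MED)
and count regression metrics (R², MAE, RMSE).

The vertical trait is the Gaussian KDE of seed y-positions with
Scott's-rule bandwidth `h = sd · n^(−1/5)`; per-genotype averages are
computed on a height-normalized 0–1000 axis, and distributions are
compared with the KL divergence `D(P‖Q) = ∫ p log(p/q) dx`.

The CNN runs on a small numpy autograd engine built into the package
(`msanet.nn`), with compact CPU backbones trained from scratch;
see `docs/methods.md` for every modeling choice and limitation.

## Worked example

```python
import numpy as np
from msanet import (ModelConfig, MSANet, TrainConfig, train, make_label,
                    downsample_labels, predict_heatmap, extract_points,
                    PeakConfig, match_points, localization_metrics)
from msanet.experiments import default_genotype_configs, simulate_cohort, build_training_items

cfgs = default_genotype_configs(seed=1)            # two contrasting genotypes
plants = simulate_cohort(cfgs, n_plants=30)        # 60 plants, 128x128
train_items = build_training_items(plants[5:])     # heatmap labels at 5 scales

model = MSANet(ModelConfig(backbone="tiny_cnn", rng_seed=1))
train(model, train_items, TrainConfig(steps=800, lr=3e-3, shuffle_seed=1))

matches = []
for plant in plants[:5]:                           # held-out plants
    heatmap = predict_heatmap(model, plant.image)
    points = extract_points(heatmap, PeakConfig(threshold=0.4, min_distance=3))
    matches.append(match_points(plant.points, points, threshold=10.0))
report = localization_metrics(matches)
print(f"F1 {report.f1:.3f}  precision {report.precision:.3f} "
      f"recall {report.recall:.3f}  MED {report.med:.2f} px")
```

Output:

```
F1 0.910  precision 0.836 recall 1.000  MED 0.51 px
```

All 122 held-out seeds are recovered (recall 1.0); after only 800 training
steps on 55 plants the model still fires on 24 soil-like distractor blobs
(precision 0.836) — the false-positive mode the fixtures are designed to
exhibit, which fades with longer training (the acceptance run below
reaches precision 0.98 at 2000 steps on 160 plants).  Matched detections
sit on average half a pixel from the annotated centroid.

The same pipeline is available as a CLI:

```sh
msanet simulate --out data --n-plants 10 --seed 1
msanet make-labels --data data --out labels
msanet train --data data --out ckpt/model.npz --steps 600
msanet predict --checkpoint ckpt/model.npz --data data --out pred
msanet evaluate --gt data --pred pred --threshold 10 --out metrics.json
msanet traits --points pred --out traits/
```

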