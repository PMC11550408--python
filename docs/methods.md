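# Methods

## Problem setting

The package counts and localizes seeds on images of individual mature
plants from point annotations alone: each seed is marked by a single
sub-pixel centroid (x, y), with no boxes or masks, and background clutter
(soil, stems, neighboring plants) is unannotated.  Counting is done by
detecting every seed; localization additionally feeds a vertical
seed-distribution trait that summarizes shoot architecture as a single
density curve.

## Heatmap labels

Sparse points are converted into a dense regression target in three steps:

1. **Rasterization.**  Each point becomes a 1-valued pixel (nearest pixel;
   exact .5 fractions round toward the zero origin so in-bounds coordinates
   stay in bounds).  Points that round to the same pixel merge.
2. **Dilation.**  Grey dilation with a disk structuring element of radius
   *r* grows each marker to roughly seed size,
   `H_d(x, y) = max_{(a,b) in B} H(x+a, y+b)`.
3. **Gaussian smoothing + peak normalization.**  `H_s = H_d * G` with the
   normalized isotropic Gaussian `G` of standard deviation σ, truncated at
   4σ (sub-1e-6 tail).  Plain convolution leaves isolated centers below 1,
   so the map is divided by the peak response of an isolated single point
   (same *r* and σ) and clipped to [0, 1]; isolated seed centers then equal
   exactly 1.0, and overlapping seeds saturate at 1.

Defaults are *r* = 8 px, σ = 3 px, sized for ~2000-px plant crops; the
128-px synthetic fixtures use *r* = 3, σ = 1.5.  Both are exposed
everywhere — smaller organs warrant a smaller radius.

Multi-scale targets `GT^s` are non-overlapping max pools of the label at
1/4, 1/8, 1/16, and 1/32 resolution.  Max pooling preserves the global
maximum, and since only the plant's seeds carry label mass, the 1/32 map
covers essentially the whole foreground plant — it behaves as an attention
map that tells the deep stages where the plant is.

## Network and loss

The model is an encoder–decoder.  A stride-2 stem and four stride-2 stages
yield features at 1/4, 1/8, 1/16, and 1/32 resolution.  Every enabled
stage carries a 1×1-conv + sigmoid prediction head supervised at its own
scale.  Decoding runs deepest-first: each stage's one-channel prediction is
upsampled ×2 (nearest neighbor) and concatenated with the next shallower
stage's features before that stage's head.  The final head combines the
×4-upsampled 1/4-scale prediction with a shallow full-resolution stem
feature through a 3×3 conv + ReLU + 1×1 conv + sigmoid to emit the output
map P.  Loss terms are plain per-pixel MSE:

    L_seg = MSE(GT, P)
    L_ms  = Σ_{s ∈ S} MSE(GT^s, P^s)
    L     = L_seg + λ·L_ms,    λ = 1 by default.

Design choices that were genuinely open and are fixed here:

* **Sigmoid outputs** keep predictions in [0, 1] like the labels; MSE
  against bounded targets motivates a bounded output.
* **Decoder wiring**: per-stage heads see features plus the upsampled
  deeper *prediction* (one channel), the minimal structure consistent with
  prediction-map skip connections; whether the full-resolution head is
  distinct from the 1/4 head was ambiguous, and a distinct shallow
  refinement head was chosen.
* **Backbones** are compact CNN encoders (`tiny_cnn`, ~8k parameters;
  `base_cnn`, wider) trained from scratch on a numpy autograd engine built
  into the package (im2col convolution, nearest-neighbor upsampling,
  channel concat, AdamW).  No pretrained weights exist for them, so
  `pretrained=True` is rejected.  The engine is gradient-checked against
  central finite differences in the test suite.
* **Optimizer** AdamW, lr 3e-3 for the tiny backbone, weight decay 1e-5,
  no augmentation; all logged per run.

Training uses batch size exactly one at native resolution.  A four-stage
stride-32 encoder needs divisibility by 32, so images are reflect-padded
and labels zero-padded to the next multiple of 32, and predictions cropped
back; zero-padded label regions contribute no gradient signal toward false
structure.

### Stage blocking (ablation)

`block_stages` removes stages deepest-first; blocking all four leaves a
raw-resolution-only model whose loss is `L_seg` alone.  The ablation
harness trains full and raw-only models on identical fixtures over three
seeded repeats and compares mean held-out F1.

## Readout

The readout of discrete points from a predicted heatmap is not part of the
original formulation and is defined here: candidate peaks are connected
plateaus of local maxima (8-connectivity) contributing their centroid
once; candidates with value ≥ τ (default 0.4) are visited in descending
value (ties: row, then column) and kept greedily at pairwise separation ≥
`min_distance` (default = the label dilation radius).  Raising τ can only
remove candidates, so the extracted count is monotone non-increasing in τ.
The operator is validated by a label-roundtrip oracle: constructing a
label from well-separated points and extracting peaks recovers every point
to within 1 px.

## Evaluation protocol

Matching is globally greedy: all GT–prediction pairs within the threshold
(default 25 px, matching typical neighbor-seed spacing at full image
scale) are sorted by ascending distance (ties: GT index, prediction
index) and accepted when both endpoints are free.  This is deterministic,
one-to-one, and maximal, unlike naive per-point nearest neighbor, which
can double-assign.  Matched pairs are TPs; unmatched predictions FPs;
unmatched GT points FNs.

* Per-image MED = mean pair distance; dataset MED averages per-image MEDs
  over images with ≥ 1 pair (match-free images are excluded and counted —
  the per-image mean is undefined at zero pairs).
* Precision, recall, F1 are computed from TP/FP/FN pooled over the
  dataset; per-image values are also reported since either aggregation
  scope is defensible.
* Counting metrics over per-image counts: MAE, RMSE, and R² about the mean
  GT count.  Zero-variance GT counts leave R² undefined, reported
  explicitly as such rather than as a silent NaN.

## Vertical seed-distribution trait

Per plant, the Gaussian KDE of seed y-positions (image y, increasing
downward) on a grid spanning the data ± 4h, with Scott's-rule bandwidth
h = sd·n^(−1/5) (unbiased sd; n ≥ 2 required, otherwise an explicit
bandwidth must be supplied).  For genotype-level comparison each plant's
seed-y extent (min to max seed y, the least-assumptive anchor) is mapped
linearly to 0–1000, per-plant profiles are interpolated onto a shared
grid, averaged pointwise, and rescaled to integrate to 1.  KL divergence
D(P‖Q) = ∫ p log(p/q) is computed by trapezoid quadrature on the union
grid with q floored at 1e-12 (the integral is improper where q → 0);
values within 1e-9 below zero are clamped to 0.  Grid resolution defaults
to 512 points.

## Synthetic fixtures

The generator emulates the features the pipeline is sensitive to, not
photorealism: seed-like tan elliptical blobs (radius 2–3.2 px at fixture
scale) whose exact centroids are the annotations; y-positions drawn from a
per-genotype mixture of truncated normals (the quantity the trait must
recover); x-positions concentrated around a rendered stem polyline;
textured background noise; and unannotated soil-like distractor blobs of
the same size class.  Distractors carry a slightly shifted hue and are
placed in the soil bands beside the plant, so they are locally
confusable with seeds and reliably separable only through spatial
context — this reproduces the dominant false-positive mode (soil
misidentified as seed) and gives the stage-blocking ablation something to
measure: a raw-resolution-only model must rely on local color, while the
multi-scale stages see where the plant is.

Placement uses rejection sampling with a 10,000-attempt budget and a
minimum center separation (8 px default at fixture scale), erroring out
rather than silently violating the requested density.  Everything is
deterministic given the config seed, including rendered PNG bytes and the
YAML manifest, which suffices to regenerate a fixture set byte-identically.

`PlantSimConfig.n_seeds_range` optionally draws each plant's seed count
uniformly from a range (default 15–35 in the experiment conditions);
without count variance across plants the counting R² would be undefined.

### What the fixtures do not show

Fixture results demonstrate that the pipeline's machinery is correct and
that the architecture can exploit multi-scale context; they do not
demonstrate field-scale accuracy.  Real imagery has occlusion between
pods, lighting variation, motion blur, genotype-dependent seed appearance,
and ~2000-px resolution with a pretrained large backbone — none of which
the 128-px fixtures model.  Published-scale numbers on field datasets are
out of scope here.

## Experiment conditions

The end-to-end recovery experiment uses 200 plants (100 per genotype,
two genotypes with mirrored bimodal vertical mixtures centered at 0.30/0.62
and 0.38/0.70 of plant height), 128×128 images, a 160/40 train/test split,
2000 training steps of the tiny backbone, peak readout at τ = 0.4 and
min-distance 3, and point matching at 10 px — the fixture-scale analog of
the 25-px threshold, since fixture seeds are ~8 px apart where real
neighboring seeds are ~25 px apart.  The ablation comparison uses 40
plants (12 test) per repeat at 96×96 and 600 steps, three repeats.  These
sizes keep a full run on one CPU in tens of seconds while leaving the
measured quantities (F1, R², KL) well away from their floor/ceiling.

## Known limitations

* The convolutional engine is single-threaded numpy; it is sized for
  fixture-scale experiments, not for ~2000-px field crops.
* The 25-px matching threshold and the dilation radius are image-scale
  dependent; both are configuration values, not constants.
* Scott's rule assumes roughly unimodal dispersion; strongly multimodal
  seed distributions get slightly oversmoothed profiles (the genotype
  averages here are still well separated).
* The peak readout assumes approximately isotropic peaks; strongly
  elongated or merged seed clusters may be read as one point.
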