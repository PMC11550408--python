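"""Multi-scale encoder-decoder for heatmap regression, its loss, and training.

The encoder downsamples the image across four stride-2 stages (after a
stride-2 stem), yielding feature maps at 1/4, 1/8, 1/16, and 1/32 of the
input resolution.  Each enabled stage carries a sigmoid prediction head
supervised by the max-pooled label at that scale; decoding proceeds from the
deepest enabled stage upward, upsampling each stage's one-channel prediction
by nearest-neighbor interpolation and concatenating it with the next
shallower stage's features before that stage's head.  A final
full-resolution head combines the upsampled 1/4-scale prediction with a
shallow full-resolution stem feature to emit the output map P.

Training loss (with per-pixel MSE at every scale):

    L_seg = MSE(GT, P)            full resolution
    L_ms  = sum_s MSE(GT^s, P^s)  over enabled stages s
    L     = L_seg + lambda * L_ms   (lambda defaults to 1)

Training runs with batch size one at native resolution (inputs padded to a
multiple of 32, the deepest stride, and predictions cropped back).  The
stage-blocking ablation removes stages from the deepest upward; blocking all
four leaves a raw-resolution-only model whose loss is L_seg alone.

Backbones are compact CNN encoders trained from scratch on the CPU autograd
engine in :mod:`msanet.nn`; no pretrained weights are available, so
``pretrained=True`` is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from msanet.errors import ConfigError, ValidationError
from msanet.heatmaps import MultiScaleLabels, pad_to_multiple
from msanet.nn import (
    AdamW,
    Tensor,
    add,
    concat_channels,
    conv2d,
    mse,
    relu,
    scale,
    sigmoid,
    upsample_nearest,
)

STAGE_DIVISORS = (4, 8, 16, 32)

# channel widths: (full-res stem feature, 1/2 stem, stage 1/4, 1/8, 1/16, 1/32)
BACKBONES = {
    "tiny_cnn": (8, 8, 12, 16, 16, 16),
    "base_cnn": (16, 16, 24, 32, 48, 48),
}


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny_cnn"
    pretrained: bool = False
    enabled_stages: frozenset[int] = frozenset(STAGE_DIVISORS)
    raw_only: bool = False
    head_channels: int = 8
    lambda_ms: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigError(
                f"unknown backbone {self.backbone!r}; available: {sorted(BACKBONES)}"
            )
        if self.pretrained:
            raise ConfigError(
                "pretrained weights are not available for the CPU backbones; "
                "set pretrained=False"
            )
        stages = frozenset(int(s) for s in self.enabled_stages)
        bad = stages - set(STAGE_DIVISORS)
        if bad:
            raise ConfigError(f"unknown stage divisors {sorted(bad)}; valid: {STAGE_DIVISORS}")
        object.__setattr__(self, "enabled_stages", stages)
        if not stages and not self.raw_only:
            raise ConfigError(
                "enabled_stages is empty; set raw_only=True for the raw-resolution-only mode"
            )
        if self.lambda_ms < 0:
            raise ConfigError(f"lambda_ms must be >= 0, got {self.lambda_ms}")


def block_stages(cfg: ModelConfig, blocked: Sequence[int] | set[int]) -> ModelConfig:
    """Return a config with the given stage divisors removed (idempotent).

    Blocking all four stages yields the raw-resolution-only ablation mode in
    which the loss reduces to L_seg.
    """
    blocked = {int(b) for b in blocked}
    bad = blocked - set(STAGE_DIVISORS)
    if bad:
        raise ValidationError(f"cannot block unknown stage divisors {sorted(bad)}")
    remaining = frozenset(cfg.enabled_stages - blocked)
    return replace(cfg, enabled_stages=remaining, raw_only=not remaining)


@dataclass
class MultiScalePrediction:
    """Per-stage sigmoid maps plus the full-resolution output, all in [0, 1]."""

    stage_maps: dict[int, np.ndarray]
    full_map: np.ndarray


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class _Conv:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int, stride: int):
        self.weight = Tensor(_he_init(rng, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride)

    @property
    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]


class MSANet:
    """The multi-scale heatmap-regression network."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        c_full, c_half, c4, c8, c16, c32 = BACKBONES[cfg.backbone]
        self.stage_channels = {4: c4, 8: c8, 16: c16, 32: c32}

        self.stem_full = _Conv(rng, 3, c_full, 3, 1)
        self.stem_half = _Conv(rng, 3, c_half, 3, 2)
        self.enc = {
            4: _Conv(rng, c_half, c4, 3, 2),
            8: _Conv(rng, c4, c8, 3, 2),
            16: _Conv(rng, c8, c16, 3, 2),
            32: _Conv(rng, c16, c32, 3, 2),
        }

        # deepest-first decoding order over enabled stages
        self.decode_order = sorted(cfg.enabled_stages, reverse=True)
        self.heads = {}
        prev: Optional[int] = None
        for k in self.decode_order:
            extra = 0 if prev is None else 1  # upsampled deeper prediction channel
            self.heads[k] = _Conv(rng, self.stage_channels[k] + extra, 1, 1, 1)
            prev = k

        full_in = c_full + (1 if self.decode_order else 0)
        self.final_mix = _Conv(rng, full_in, cfg.head_channels, 3, 1)
        self.final_head = _Conv(rng, cfg.head_channels, 1, 1, 1)

    def parameters(self) -> list[Tensor]:
        layers = [self.stem_full, self.stem_half, *self.enc.values(), *self.heads.values(),
                  self.final_mix, self.final_head]
        return [p for layer in layers for p in layer.params]

    def forward(self, image: np.ndarray) -> tuple[dict[int, Tensor], Tensor]:
        """Run the network on a (H, W, 3) float image in [0, 1].

        H and W must be multiples of 32.  Returns per-stage prediction
        tensors (keyed by divisor) and the full-resolution output tensor.
        """
        h, w = image.shape[:2]
        if h % 32 or w % 32:
            raise ValidationError(f"input {h}x{w} not a multiple of 32; pad first")
        x = Tensor(np.ascontiguousarray(image.transpose(2, 0, 1)))

        f_full = relu(self.stem_full(x))
        feat = relu(self.stem_half(x))
        features: dict[int, Tensor] = {}
        for k in STAGE_DIVISORS:
            feat = relu(self.enc[k](feat))
            features[k] = feat

        stage_preds: dict[int, Tensor] = {}
        carry: Optional[Tensor] = None
        carry_div: Optional[int] = None
        for k in self.decode_order:
            inp = features[k]
            if carry is not None:
                inp = concat_channels([inp, upsample_nearest(carry, carry_div // k)])
            pred = sigmoid(self.heads[k](inp))
            stage_preds[k] = pred
            carry, carry_div = pred, k

        full_in = f_full
        if carry is not None:
            full_in = concat_channels([f_full, upsample_nearest(carry, carry_div)])
        full = sigmoid(self.final_head(relu(self.final_mix(full_in))))
        return stage_preds, full

    def predict(self, image: np.ndarray) -> MultiScalePrediction:
        """Inference forward pass returning plain numpy maps."""
        stage_preds, full = self.forward(image)
        return MultiScalePrediction(
            stage_maps={k: t.data[0] for k, t in stage_preds.items()},
            full_map=full.data[0],
        )

    # --- checkpointing -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **self.state_arrays())
        cfg = self.cfg
        meta = {
            "backbone": cfg.backbone,
            "enabled_stages": sorted(cfg.enabled_stages),
            "raw_only": cfg.raw_only,
            "head_channels": cfg.head_channels,
            "lambda_ms": cfg.lambda_ms,
            "rng_seed": cfg.rng_seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "MSANet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(
            backbone=meta["backbone"],
            enabled_stages=frozenset(meta["enabled_stages"]),
            raw_only=meta["raw_only"],
            head_channels=meta["head_channels"],
            lambda_ms=meta["lambda_ms"],
            rng_seed=meta["rng_seed"],
        )
        model = cls(cfg)
        npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        with np.load(npz_path) as data:
            for i, p in enumerate(model.parameters()):
                p.data[...] = data[f"p{i}"]
        return model


def compute_loss(
    pred: MultiScalePrediction, labels: MultiScaleLabels, lambda_ms: float = 1.0
) -> tuple[float, float, float]:
    """Numeric (L, L_seg, L_ms) from numpy maps; mirrors the training loss."""
    gt_full = labels.maps[1]
    if pred.full_map.shape != gt_full.shape:
        raise ValidationError(
            f"full-resolution shape mismatch: pred {pred.full_map.shape} vs label {gt_full.shape}"
        )
    l_seg = float(((gt_full - pred.full_map) ** 2).mean())
    l_ms = 0.0
    for k, p in sorted(pred.stage_maps.items()):
        gt = labels.maps.get(k)
        if gt is None or gt.shape != p.shape:
            raise ValidationError(f"label missing or misshapen at scale 1/{k}")
        l_ms += float(((gt - p) ** 2).mean())
    return l_seg + lambda_ms * l_ms, l_seg, l_ms


def _loss_tensor(
    stage_preds: dict[int, Tensor], full: Tensor, labels: MultiScaleLabels, lambda_ms: float
) -> Tensor:
    total = mse(full, labels.maps[1][None])
    if stage_preds and lambda_ms > 0:
        l_ms: Optional[Tensor] = None
        for k in sorted(stage_preds):
            term = mse(stage_preds[k], labels.maps[k][None])
            l_ms = term if l_ms is None else add(l_ms, term)
        total = add(total, scale(l_ms, lambda_ms))
    return total


@dataclass
class TrainConfig:
    steps: int = 1000
    lr: float = 3e-3
    weight_decay: float = 1e-5
    lambda_ms: Optional[float] = None  # default: ModelConfig.lambda_ms
    shuffle_seed: int = 0
    log_every: int = 0  # 0 = silent


def prepare_sample(
    image: np.ndarray, labels: MultiScaleLabels
) -> tuple[np.ndarray, MultiScaleLabels]:
    """Reflect-pad the image and zero-pad the full-res label to multiples of 32.

    Stage maps are recomputed from the padded label by the caller if needed;
    here labels are assumed built from an already padded full-resolution map.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError("expected an RGB image (H, W, 3)")
    if img.max() > 1.0:
        img = img / 255.0
    img, _ = pad_to_multiple(img, 32, mode="reflect")
    return img, labels


def train(
    model: MSANet,
    dataset: Sequence[tuple[np.ndarray, MultiScaleLabels]],
    opts: TrainConfig = TrainConfig(),
) -> list[float]:
    """Batch-size-1 training at native resolution; returns the per-step loss history.

    Iterates over the dataset in reshuffled epochs (deterministic given
    ``shuffle_seed``).  Aborts on a non-finite loss.
    """
    if not dataset:
        raise ValidationError("empty training dataset")
    lam = model.cfg.lambda_ms if opts.lambda_ms is None else opts.lambda_ms
    params = model.parameters()
    optim = AdamW(params, lr=opts.lr, weight_decay=opts.weight_decay)
    rng = np.random.default_rng(opts.shuffle_seed)

    history: list[float] = []
    order: list[int] = []
    for step in range(opts.steps):
        if not order:
            order = list(rng.permutation(len(dataset)))
        idx = order.pop()
        image, labels = dataset[idx]
        img = np.asarray(image, dtype=np.float64)
        if img.max() > 1.0:
            img = img / 255.0
        stage_preds, full = model.forward(img)
        loss = _loss_tensor(stage_preds, full, labels, lam)
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite loss {value} at step {step}; aborting")
        history.append(value)
        optim.zero_grad()
        loss.backward()
        optim.step()
        if opts.log_every and (step + 1) % opts.log_every == 0:
            recent = history[-opts.log_every :]
            print(f"step {step + 1}/{opts.steps}  loss {np.mean(recent):.5f}")
    return history
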