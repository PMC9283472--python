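"""Weight-adaptive multitask segmentation network.

A shared encoder of multilevel dilated residual (MDR) blocks feeds a
bottleneck of parallel dilated convolutions (default rates 1, 3, 5) and two
structurally identical but parameter-independent decoders — one for the
breast area, one for the dense tissue.  Decoders upsample with stride-2
transpose convolutions, concatenate the matching encoder features (skip
connections), and run an MDR block with a residual shortcut.  Each head is
a 1x1 convolution with a per-pixel two-class softmax (background, region
of interest).

The MDR block used here is: parallel 3x3 convolutions at the configured
dilation rates, each preceded by normalization + ReLU, concatenated and
fused by a 1x1 convolution, plus an identity (or 1x1 projection) shortcut.
The exact internal wiring of the original block is not fully published, so
this wiring is an explicit, documented assumption (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .losses import TaskUncertainty

__all__ = [
    "NetworkConfig",
    "ProbabilityMaps",
    "MultiTaskSegNet",
    "ModelState",
    "MDRBlock",
    "Bottleneck",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

HEADS = ("breast", "dense")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` counts 2x down-samplings; channel width doubles per stage
    from ``base_width``.  ``bottleneck_dilations`` are the parallel rates
    of the bottleneck; ``block_dilations`` those inside each MDR block.
    """

    in_channels: int = 1
    input_side: int = 256
    depth: int = 4
    base_width: int = 64
    bottleneck_dilations: tuple[int, ...] = (1, 3, 5)
    block_dilations: tuple[int, ...] = (1, 3)
    norm_layer: str = "batch"
    classes_per_head: int = 2
    heads: tuple[str, ...] = HEADS
    merge: str = "concat"

    def __post_init__(self):
        if self.depth < 1 or self.base_width < 1:
            raise ValueError("depth and base_width must be >= 1")
        for rates in (self.bottleneck_dilations, self.block_dilations):
            if any(d <= 0 for d in rates) or list(rates) != sorted(set(rates)):
                raise ValueError("dilation rates must be positive, strictly increasing")
        if self.classes_per_head != 2:
            raise ValueError("heads are two-class (ROI vs background) by design")
        if self.input_side % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by 2^depth={2**self.depth}")
        if not self.heads or any(h not in HEADS for h in self.heads):
            raise ValueError(f"heads must be a non-empty subset of {HEADS}")


@dataclass
class ProbabilityMaps:
    """Per-task class-probability grids, shape (H, W, 2), channel 1 = ROI."""

    breast: np.ndarray | None = None
    dense: np.ndarray | None = None
    logits: dict | None = None

    def roi(self, head: str) -> np.ndarray:
        arr = getattr(self, head)
        if arr is None:
            raise KeyError(f"model has no '{head}' head")
        return arr[..., 1]


class MDRBlock(nn.Module):
    """Multilevel dilated residual block (same spatial size in and out)."""

    def __init__(self, in_ch, out_ch, dilations, norm, rng, weight_standardize=False):
        super().__init__()
        self.branches = nn.ModuleList([
            nn.Sequential(
                nn.make_norm(norm, in_ch),
                nn.ReLU(),
                nn.Conv2d(in_ch, out_ch, 3, dilation=d, rng=rng,
                          weight_standardize=weight_standardize),
            )
            for d in dilations
        ])
        self.fuse = nn.Conv2d(out_ch * len(dilations), out_ch, 1, rng=rng)
        self.project = None if in_ch == out_ch else nn.Conv2d(in_ch, out_ch, 1, rng=rng)

    def forward(self, x):
        feats = [b(x) for b in self.branches]
        merged = self.fuse(nn.concat(feats, axis=1))
        shortcut = x if self.project is None else self.project(x)
        return merged + shortcut


class Bottleneck(nn.Module):
    """Parallel dilated 3x3 convolutions merged back to a fixed width."""

    def __init__(self, in_ch, out_ch, dilations, norm, rng):
        super().__init__()
        self.branches = nn.ModuleList([
            nn.Sequential(
                nn.make_norm(norm, in_ch),
                nn.ReLU(),
                nn.Conv2d(in_ch, out_ch, 3, dilation=d, rng=rng),
            )
            for d in dilations
        ])
        self.fuse = nn.Conv2d(out_ch * len(dilations), out_ch, 1, rng=rng)

    def forward(self, x):
        return self.fuse(nn.concat([b(x) for b in self.branches], axis=1))


class _Decoder(nn.Module):
    def __init__(self, widths, bottleneck_width, cfg: NetworkConfig, rng):
        super().__init__()
        ws = cfg.norm_layer.lower().startswith("w")
        self.ups = nn.ModuleList()
        self.blocks = nn.ModuleList()
        cur = bottleneck_width
        for w in reversed(widths):
            self.ups.items.append(nn.ConvTranspose2d(cur, w, rng=rng))
            self.blocks.items.append(
                MDRBlock(2 * w, w, cfg.block_dilations, cfg.norm_layer, rng,
                         weight_standardize=ws))
            cur = w
        self.head = nn.Conv2d(cur, cfg.classes_per_head, 1, rng=rng)

    def forward(self, x, skips):
        for up, block, skip in zip(self.ups, self.blocks, reversed(skips)):
            x = up(x)
            x = block(nn.concat([x, skip], axis=1))
        return self.head(x)


def _softmax_channels(logits: nn.Tensor) -> nn.Tensor:
    shift = logits.data.max(axis=1, keepdims=True)  # constant shift for stability
    e = (logits - nn.Tensor(shift)).exp()
    return e / e.sum(axis=1, keepdims=True)


class MultiTaskSegNet(nn.Module):
    """Shared-encoder, two-decoder segmentation model with learnable
    per-task uncertainties attached as extra trainable scalars."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ws = config.norm_layer.lower().startswith("w")
        widths = [config.base_width * 2 ** i for i in range(config.depth)]
        bott = config.base_width * 2 ** config.depth

        self.encoder = nn.ModuleList()
        cin = config.in_channels
        for w in widths:
            self.encoder.items.append(
                MDRBlock(cin, w, config.block_dilations, config.norm_layer, rng,
                         weight_standardize=ws))
            cin = w
        self.bottleneck = Bottleneck(widths[-1], bott, config.bottleneck_dilations,
                                     config.norm_layer, rng)
        self.decoders = {h: _Decoder(widths, bott, config, rng) for h in config.heads}
        for h, dec in self.decoders.items():
            setattr(self, f"decoder_{h}", dec)
        self.uncertainty = TaskUncertainty()

    # encoder/decoder parameter views -------------------------------------
    def encoder_parameters(self):
        params = list(self.bottleneck.parameters())
        for block in self.encoder:
            params += block.parameters()
        return params

    def decoder_parameters(self, head: str):
        return self.decoders[head].parameters()

    def forward_tensors(self, x: nn.Tensor) -> dict[str, nn.Tensor]:
        """Forward pass returning per-head (B, 2, H, W) probability tensors."""
        skips = []
        h = x
        for block in self.encoder:
            h = block(h)
            skips.append(h)
            h = nn.maxpool2d(h)
        h = self.bottleneck(h)
        return {name: _softmax_channels(dec(h, skips))
                for name, dec in self.decoders.items()}

    def forward(self, x):
        return self.forward_tensors(x)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


# the model object *is* the model state: weights + uncertainty + config
ModelState = MultiTaskSegNet


def build_model(config: NetworkConfig, seed: int = 0) -> MultiTaskSegNet:
    """Build the network with He-initialized weights from `seed`."""
    return MultiTaskSegNet(config, seed=seed)


def forward(model: MultiTaskSegNet, images: np.ndarray) -> list[ProbabilityMaps]:
    """Run a batch of (B, H, W) images through the model in eval mode.

    Returns one :class:`ProbabilityMaps` per image with (H, W, 2) grids.
    """
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    side = model.config.input_side
    if arr.shape[-2:] != (side, side):
        raise ValueError(f"expected {side}x{side} inputs, got {arr.shape[-2:]}")
    was_training = model.training
    model.eval()
    try:
        out = model.forward_tensors(nn.Tensor(arr[:, None]))
    finally:
        model.train(was_training)
    maps = []
    for i in range(arr.shape[0]):
        kwargs = {}
        for head in HEADS:
            if head in out:
                kwargs[head] = np.moveaxis(out[head].data[i], 0, -1)
        maps.append(ProbabilityMaps(**kwargs))
    return maps


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: MultiTaskSegNet, path) -> Path:
    """Serialize weights, uncertainties, and the config to one .npz file."""
    path = Path(path)
    state = model.state_dict()
    meta = {
        "config": asdict(model.config),
        "s_b": float(TaskUncertainty._value(model.uncertainty.s_b)),
        "s_d": float(TaskUncertainty._value(model.uncertainty.s_d)),
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path) -> MultiTaskSegNet:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("bottleneck_dilations", "block_dilations", "heads"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = build_model(NetworkConfig(**cfg_dict))
    model.load_state_dict(state)
    model.uncertainty = TaskUncertainty(meta["s_b"], meta["s_d"])
    return model
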