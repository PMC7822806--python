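"""Encoder-decoder segmentation networks with long- and short-range skips.

Two variants are provided, both SegNet-style encoder-decoders operating on a
k-plane 2.5D slice stack and emitting per-pixel scores for the 3 classes
(background, liver, tumor) of the *center* slice:

``net01``
    One encoder + one decoder.  Encoder stages are residual blocks (two 3x3
    convolutions with a short additive skip, ResNet-style) followed by 2x2
    max-pooling; the decoder mirrors them with index-guided max-unpooling
    (SegNet-style) and, at each stage, a long-range connection that
    concatenates the matching encoder stage's output (U-Net-style), reconciled
    by a 1x1 adaptive convolution.

``net02``
    An expanded version: two encoder-decoder components stacked in sequence,
    the second consuming the first's decoder features, with dense long-range
    bridges from the first component's encoder stages into the second
    component's decoder stages.

Channel widths double at each pooling stage starting from ``base_channels``.
Short and long skips can be disabled individually (ablation switches).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .sampling import SliceStack

NETWORK_VARIANTS = ("net01", "net02")


@dataclass
class NetworkConfig:
    variant: str = "net01"
    in_planes: int = 3  # stack size k, odd
    num_classes: int = 3
    base_channels: int = 32
    depth: int = 3  # number of pooling stages
    use_short_skips: bool = True
    use_long_skips: bool = True
    upsample_mode: str = "max_unpool"  # max_unpool | tconv | nearest
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in NETWORK_VARIANTS:
            raise ValueError(f"variant must be one of {NETWORK_VARIANTS}, got {self.variant!r}")
        if self.upsample_mode not in ("max_unpool", "tconv", "nearest"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.in_planes % 2 == 0 or self.in_planes < 1:
            raise ValueError(f"in_planes must be odd and >= 1, got {self.in_planes}")
        if self.num_classes != 3:
            raise ValueError("this pipeline segments exactly 3 classes (background/liver/tumor)")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.depth))


@dataclass
class ClassScoreMap:
    """Per-pixel class scores (and probabilities) for one center slice."""

    scores: np.ndarray  # (num_classes, H, W)
    probabilities: np.ndarray  # (num_classes, H, W), sums to 1 per pixel

    def argmax_labels(self) -> np.ndarray:
        # np.argmax breaks ties toward the lower class id
        return np.argmax(self.scores, axis=0).astype(np.int16)


class _ResidualBlock:
    """conv3x3-BN-ReLU-conv3x3-BN with an additive short skip, then ReLU.

    A 1x1 adaptive convolution projects the skip when channel counts differ.
    With short skips disabled the block is a plain double convolution.
    """

    def __init__(self, cin: int, cout: int, rng, use_short: bool):
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.use_short = use_short
        if use_short and cin != cout:
            # ResNet-style projection shortcut: 1x1 conv + BN, so the skip
            # stays normalized and cannot drive a whole channel ReLU-dead.
            self.proj = nn.Conv2d(cin, cout, 1, rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def __call__(self, x, training):
        h = nn.relu(self.bn1(self.conv1(x), training))
        h = self.bn2(self.conv2(h), training)
        if self.use_short:
            shortcut = self.proj_bn(self.proj(x), training) if self.proj is not None else x
            h = nn.add(h, shortcut)
        return nn.relu(h)

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            out.extend([self.proj, self.proj_bn])
        return out


class _EncoderDecoder:
    """One encoder-decoder component; returns decoder features at full resolution."""

    def __init__(self, cin: int, cfg: NetworkConfig, rng):
        ch = cfg.stage_channels
        self.enc = []
        c_prev = cin
        for c in ch:
            self.enc.append(_ResidualBlock(c_prev, c, rng, cfg.use_short_skips))
            c_prev = c
        self.bottleneck = _ResidualBlock(ch[-1], ch[-1], rng, cfg.use_short_skips)
        # Decoder, indexed by encoder stage.  Before unpooling at stage i the
        # feature map must carry ch[i] channels (the unpooling indices were
        # recorded there), so each decoder block reduces to the next stage's
        # width on the way up.
        self.dec: dict[int, _ResidualBlock] = {}
        self.fuse: dict[int, nn.Conv2d] = {}  # 1x1 adaptive convs after long-range concat
        self.upsample: dict[int, nn.ConvTranspose2x2] = {}  # tconv mode only
        self.use_long = cfg.use_long_skips
        self.upsample_mode = cfg.upsample_mode
        for i in reversed(range(len(ch))):
            if cfg.upsample_mode == "tconv":
                self.upsample[i] = nn.ConvTranspose2x2(ch[i], ch[i], rng)
            if self.use_long:
                self.fuse[i] = nn.Conv2d(2 * ch[i], ch[i], 1, rng)
            cout = ch[i - 1] if i > 0 else ch[0]
            self.dec[i] = _ResidualBlock(ch[i], cout, rng, cfg.use_short_skips)
        self.out_channels = ch[0]

    def __call__(self, x, training, extra_skips=None):
        """``extra_skips``: optional per-stage feature list (same shapes as this
        component's encoder outputs) added into the decoder's long-range merge —
        the dense bridges of the two-component variant."""
        skips, indices = [], []
        h = x
        for block in self.enc:
            h = block(h, training)
            skips.append(h)
            pooled, idx = nn.max_pool2x2(h)
            indices.append(idx)
            h = pooled
        h = self.bottleneck(h, training)
        for stage in reversed(range(len(self.enc))):
            if self.upsample_mode == "max_unpool":
                h = nn.max_unpool2x2(h, indices[stage])
            elif self.upsample_mode == "tconv":
                h = self.upsample[stage](h)
            else:  # nearest
                h = nn.upsample_nearest2x2(h)
            if self.use_long:
                skip = skips[stage]
                if extra_skips is not None:
                    skip = nn.add(skip, extra_skips[stage])
                h = self.fuse[stage](nn.concat(h, skip))
            h = self.dec[stage](h, training)
        return h, skips

    def layers(self):
        out = []
        for b in self.enc:
            out.extend(b.layers())
        out.extend(self.bottleneck.layers())
        for i in sorted(self.dec):
            out.extend(self.dec[i].layers())
        for i in sorted(self.fuse):
            out.append(self.fuse[i])
        for i in sorted(self.upsample):
            out.append(self.upsample[i])
        return out


class SegmentationNetwork:
    """Net01 / Net02 segmentation network over 2.5D slice stacks."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        self.comp1 = _EncoderDecoder(cfg.in_planes, cfg, rng)
        if cfg.variant == "net02":
            self.comp2 = _EncoderDecoder(self.comp1.out_channels, cfg, rng)
        else:
            self.comp2 = None
        head_in = (self.comp2 or self.comp1).out_channels
        self.classifier = nn.Conv2d(head_in, cfg.num_classes, 1, rng, bias=True)

    # -- forward ---------------------------------------------------------

    def forward_scores(self, planes: np.ndarray, training: bool = False) -> nn.Tensor:
        """Run a batch of stacks ``(N, k, H, W)`` to logits ``(N, 3, H, W)``."""
        planes = np.asarray(planes, dtype=np.float64)
        if planes.ndim == 3:
            planes = planes[None]
        n, k, h, w = planes.shape
        if k != self.cfg.in_planes:
            raise ValueError(f"network expects stacks of {self.cfg.in_planes} planes, got {k}")
        div = 2**self.cfg.depth
        if h % div or w % div:
            raise ValueError(f"spatial size ({h}, {w}) must be divisible by 2^depth = {div}")
        x = nn.Tensor(planes / 255.0)  # bring grayscale input to unit scale
        feats, skips1 = self.comp1(x, training)
        if self.comp2 is not None:
            feats, _ = self.comp2(feats, training, extra_skips=skips1)
        return self.classifier(feats)

    def predict(self, stack: SliceStack) -> ClassScoreMap:
        """Score one stack in evaluation mode (deterministic given weights)."""
        scores = self.forward_scores(stack.planes[None], training=False).data[0]
        return ClassScoreMap(scores=scores, probabilities=nn.softmax(scores, axis=0))

    def predict_batch(self, planes: np.ndarray) -> np.ndarray:
        """Argmax labels for a batch of stacks, ties toward the lower class id."""
        scores = self.forward_scores(planes, training=False).data
        return np.argmax(scores, axis=1).astype(np.int16)

    # -- parameters ------------------------------------------------------

    def layers(self):
        out = self.comp1.layers()
        if self.comp2 is not None:
            out.extend(self.comp2.layers())
        out.append(self.classifier)
        return out

    def parameter_arrays(self) -> list[np.ndarray]:
        return [getattr(owner, name) for layer in self.layers() for owner, name in layer.parameters()]

    def num_parameters(self) -> int:
        return int(sum(a.size for a in self.parameter_arrays()))

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = {
            "format_version": 1,
            "config": asdict(self.cfg),
            "params": self.parameter_arrays(),
            "bn_stats": [
                (l.running_mean.copy(), l.running_var.copy())
                for l in self.layers()
                if isinstance(l, nn.BatchNorm2d)
            ],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationNetwork":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        net = cls(NetworkConfig(**state["config"]))
        for cur, saved in zip(net.parameter_arrays(), state["params"]):
            cur[...] = saved
        bn_layers = [l for l in net.layers() if isinstance(l, nn.BatchNorm2d)]
        for l, (rm, rv) in zip(bn_layers, state["bn_stats"]):
            l.running_mean[...] = rm
            l.running_var[...] = rv
        return net


def build_network(cfg: NetworkConfig) -> SegmentationNetwork:
    """Construct a Net01 or Net02 with seeded weight initialization."""
    return SegmentationNetwork(cfg)


def forward(network: SegmentationNetwork, stack: SliceStack) -> ClassScoreMap:
    """Score one slice stack; probabilities are softmax-normalized per pixel."""
    return network.predict(stack)
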