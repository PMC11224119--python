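"""SDC-DeepLabv3+ — lightweight encoder-decoder segmentation network.

Encoder: a ShuffleNetV2 backbone (channel split / channel shuffle units)
feeding an atrous-spatial-pyramid-pooling head built from dilated
depthwise-separable convolutions at rates 3, 6, 9, 12, 15, 18 with a
64-channel bottleneck (DDSC-ASPP).  Convolutional block attention (CBAM,
channel-then-spatial) gates the encoder output and the shallow feature
before decoder fusion.  Decoder: 1x1 reduction, 4x bilinear upsampling,
fusion with the stride-4 shallow feature, 3x3 convolution and a final 4x
upsampling to per-pixel logits over the four scene classes
(background / filament / fruit ball / branch).

The deep feature is kept at output stride 16 by running the last backbone
stage at stride 1 with dilation 2; the shallow feature is tapped at the only
stride-4 point of the backbone, right after the stem and max-pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import BadGroupsError, FusionShapeError, InputShapeError, OddChannelsError
from . import autodiff as ad
from .autodiff import Tensor
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    DepthwiseSeparableConv,
    Module,
    Parameter,
    ReLU,
    Sequential,
)

_STAGE_CHANNELS = {0.5: (48, 96, 192), 1.0: (116, 232, 464)}
STEM_CHANNELS = 24


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``width_multiplier`` selects the backbone channel budget (0.5x or 1x);
    ``dilation_rates`` are the sampling rates of the six dilated ASPP
    branches; the ASPP bottleneck reduces each dilated branch to 64 channels
    before two cascaded 3x3 depthwise-separable convolutions and re-expansion
    to ``aspp_out``.
    """

    width_multiplier: float = 0.5
    num_classes: int = 4
    dilation_rates: tuple = (3, 6, 9, 12, 15, 18)
    aspp_bottleneck: int = 64
    aspp_out: int = 256
    stage_repeats: tuple = (4, 8, 4)
    decoder_channels: int = 128
    cbam_reduction: int = 8

    def __post_init__(self):
        if self.width_multiplier not in _STAGE_CHANNELS:
            raise ValueError("width_multiplier must be 0.5 or 1.0")
        rates = self.dilation_rates
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dilation rates must be strictly increasing")
        if self.aspp_bottleneck >= self.aspp_out:
            raise ValueError("aspp bottleneck must be smaller than aspp_out")
        if len(self.stage_repeats) != 3 or any(r < 1 for r in self.stage_repeats):
            raise ValueError("stage_repeats must be three positive counts")

    @property
    def stage_channels(self) -> tuple:
        return _STAGE_CHANNELS[self.width_multiplier]

    def to_dict(self) -> dict:
        return {
            "width_multiplier": self.width_multiplier,
            "num_classes": self.num_classes,
            "dilation_rates": list(self.dilation_rates),
            "aspp_bottleneck": self.aspp_bottleneck,
            "aspp_out": self.aspp_out,
            "stage_repeats": list(self.stage_repeats),
            "decoder_channels": self.decoder_channels,
            "cbam_reduction": self.cbam_reduction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("dilation_rates", "stage_repeats"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# -- receptive-field arithmetic ------------------------------------------

def receptive_field(r: int, k: int) -> int:
    """Receptive field of a k×k convolution dilated by r: (r−1)(k−1)+k."""
    if r < 1 or k < 1:
        raise ValueError("dilation rate and kernel size must be >= 1")
    return (r - 1) * (k - 1) + k


def cascade_receptive_field(r1: int, r2: int) -> int:
    """Receptive field of two cascaded layers with fields R1, R2: R1+R2−1."""
    if r1 < 1 or r2 < 1:
        raise ValueError("receptive fields must be >= 1")
    return r1 + r2 - 1


# -- channel split / shuffle ---------------------------------------------

def _wrap(x):
    """Accept a Tensor, an (N,C,H,W) array or a (C,H,W) array."""
    if isinstance(x, Tensor):
        return x, "tensor"
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 3:
        return Tensor(arr[None]), "chw"
    return Tensor(arr), "nchw"


def _unwrap(t: Tensor, kind: str):
    if kind == "tensor":
        return t
    return t.data[0] if kind == "chw" else t.data


def channel_split(x):
    """Split the channel axis into two equal halves (stride-1 unit input)."""
    t, kind = _wrap(x)
    c = t.data.shape[1]
    if c % 2 != 0:
        raise OddChannelsError(f"channel_split needs an even channel count, got {c}")
    half = c // 2
    a = ad.narrow_channels(t, 0, half)
    b = ad.narrow_channels(t, half, half)
    return _unwrap(a, kind), _unwrap(b, kind)


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The fixed channel permutation: reshape (g, c/g), transpose, flatten."""
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def channel_shuffle(x, groups: int):
    """Interleave channel groups so split branches exchange information."""
    t, kind = _wrap(x)
    c = t.data.shape[1]
    if groups < 1 or c % groups != 0:
        raise BadGroupsError(f"{c} channels not divisible into {groups} groups")
    out = ad.permute_channels(t, shuffle_permutation(c, groups))
    return _unwrap(out, kind)


# -- backbone blocks ------------------------------------------------------

class ShuffleUnitS1(Module):
    """Stride-1 unit: split, transform one half, concat, shuffle."""

    def __init__(self, channels: int, rng):
        super().__init__()
        if channels % 2 != 0:
            raise OddChannelsError("stride-1 unit needs an even channel count")
        half = channels // 2
        self.branch = Sequential(
            ConvBNReLU(half, half, 1, rng),
            Conv2d(half, half, 3, groups=half, bias=False, rng=rng),
            BatchNorm2d(half),
            ConvBNReLU(half, half, 1, rng),
        )

    def forward(self, x):
        left, right = channel_split(x)
        out = ad.concat([left, self.branch(right)], axis=1)
        return channel_shuffle(out, 2)


class ShuffleUnitS2(Module):
    """Downsampling unit: no split, both branches transform the input.

    ``stride`` may be forced to 1 (with ``dilation``) to hold the output
    stride at 16 in the last backbone stage, DeepLab-style.
    """

    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 2, dilation: int = 1):
        super().__init__()
        half = out_ch // 2
        self.branch1 = Sequential(
            Conv2d(in_ch, in_ch, 3, stride=stride, dilation=dilation,
                   groups=in_ch, bias=False, rng=rng),
            BatchNorm2d(in_ch),
            ConvBNReLU(in_ch, half, 1, rng),
        )
        self.branch2 = Sequential(
            ConvBNReLU(in_ch, half, 1, rng),
            Conv2d(half, half, 3, stride=stride, dilation=dilation,
                   groups=half, bias=False, rng=rng),
            BatchNorm2d(half),
            ConvBNReLU(half, half, 1, rng),
        )

    def forward(self, x):
        out = ad.concat([self.branch1(x), self.branch2(x)], axis=1)
        return channel_shuffle(out, 2)


class Backbone(Module):
    """ShuffleNetV2 feature extractor returning stride-4 and stride-16 maps."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.stem = ConvBNReLU(3, STEM_CHANNELS, 3, rng, stride=2)
        chans = config.stage_channels
        in_ch = STEM_CHANNELS
        stages = []
        for i, (out_ch, repeats) in enumerate(zip(chans, config.stage_repeats)):
            last = i == len(chans) - 1
            units = [ShuffleUnitS2(in_ch, out_ch, rng,
                                   stride=1 if last else 2,
                                   dilation=2 if last else 1)]
            units += [ShuffleUnitS1(out_ch, rng) for _ in range(repeats - 1)]
            stages.append(Sequential(*units))
            in_ch = out_ch
        self.stages = stages
        self.out_channels = in_ch
        self.shallow_channels = STEM_CHANNELS

    def forward(self, x):
        h, w = x.data.shape[2:]
        if h % 16 or w % 16:
            raise InputShapeError(f"input height/width must be divisible by 16, got {h}x{w}")
        x = self.stem(x)
        x = ad.maxpool2d(x, kernel=3, stride=2, padding=1)
        shallow = x  # stride 4, 24 channels
        for stage in self.stages:
            x = stage(x)
        return shallow, x  # deep: stride 16


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate."""

    def __init__(self, channels: int, rng, reduction: int = 8, spatial_kernel: int = 7):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, bias=True, rng=rng)
        self.spatial = Conv2d(2, 1, spatial_kernel, bias=True, rng=rng)

    def channel_gate(self, x):
        avg = self.fc2(ad.relu(self.fc1(ad.spatial_mean(x))))
        mx = self.fc2(ad.relu(self.fc1(ad.spatial_max(x))))
        return ad.sigmoid(avg + mx)  # (N, C, 1, 1)

    def spatial_gate(self, x):
        pooled = ad.concat([ad.channel_mean(x), ad.channel_max(x)], axis=1)
        return ad.sigmoid(self.spatial(pooled))  # (N, 1, H, W)

    def forward(self, x):
        x = x * self.channel_gate(x)
        return x * self.spatial_gate(x)


class _DilatedBranch(Module):
    """Bottleneck + two cascaded dilated depthwise-separable 3x3 convs."""

    def __init__(self, in_ch: int, rate: int, bottleneck: int, out_ch: int, rng):
        super().__init__()
        self.rate = rate
        self.body = Sequential(
            ConvBNReLU(in_ch, bottleneck, 1, rng),
            DepthwiseSeparableConv(bottleneck, bottleneck, 3, dilation=rate, rng=rng),
            BatchNorm2d(bottleneck),
            ReLU(),
            DepthwiseSeparableConv(bottleneck, bottleneck, 3, dilation=rate, rng=rng),
            BatchNorm2d(bottleneck),
            ReLU(),
            ConvBNReLU(bottleneck, out_ch, 1, rng),
        )

    def forward(self, x):
        return self.body(x)

    def effective_receptive_field(self) -> int:
        r = receptive_field(self.rate, 3)
        return cascade_receptive_field(r, r)


class DDSCASPP(Module):
    """ASPP head with six dilated depthwise-separable branches.

    Branches: one 1x1 convolution, six dilated branches (rates from the
    model config, each a 64-channel bottleneck with two cascaded 3x3
    dilated depthwise-separable convolutions), and one global-pooling
    branch; concatenated and fused to ``aspp_out`` channels by 1x1 conv.
    """

    def __init__(self, in_ch: int, config: ModelConfig, rng):
        super().__init__()
        out = config.aspp_out
        self.conv1x1 = ConvBNReLU(in_ch, out, 1, rng)
        self.dilated = [
            _DilatedBranch(in_ch, r, config.aspp_bottleneck, out, rng)
            for r in config.dilation_rates
        ]
        self.pool_proj = Conv2d(in_ch, out, 1, bias=True, rng=rng)
        self.fuse = ConvBNReLU(out * self.branch_count, out, 1, rng)

    @property
    def branch_count(self) -> int:
        return 2 + len(self.dilated)  # 1x1 + dilated + image pooling

    def forward(self, x):
        h, w = x.data.shape[2:]
        feats = [self.conv1x1(x)]
        feats += [b(x) for b in self.dilated]
        pooled = ad.relu(self.pool_proj(ad.spatial_mean(x)))
        feats.append(ad.broadcast_hw(pooled, h, w))
        return self.fuse(ad.concat(feats, axis=1))


class Decoder(Module):
    """Fuse the ASPP output with the shallow feature and emit logits."""

    def __init__(self, shallow_ch: int, config: ModelConfig, rng):
        super().__init__()
        dc = config.decoder_channels
        self.reduce = ConvBNReLU(config.aspp_out, dc, 1, rng)
        self.cbam_shallow = CBAM(shallow_ch, rng, reduction=min(config.cbam_reduction, shallow_ch))
        self.fuse = ConvBNReLU(dc + shallow_ch, dc, 3, rng)
        # small-variance classifier init keeps early logits near the prior
        self.classifier = Conv2d(dc, config.num_classes, 1, bias=True, rng=rng,
                                 init_std=0.01)

    def forward(self, aspp_out, shallow, out_hw):
        ah, aw = aspp_out.data.shape[2:]
        sh, sw = shallow.data.shape[2:]
        if (sh, sw) != (ah * 4, aw * 4):
            raise FusionShapeError(
                f"shallow map {sh}x{sw} is not 4x the deep map {ah}x{aw}"
            )
        x = self.reduce(aspp_out)
        x = ad.upsample_bilinear(x, sh, sw)
        s = self.cbam_shallow(shallow)
        x = self.fuse(ad.concat([x, s], axis=1))
        logits = self.classifier(x)
        return ad.upsample_bilinear(logits, *out_hw)


class SDCDeepLab(Module):
    """The full segmentation network; see the module docstring."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 42):
        super().__init__()
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.backbone = Backbone(self.config, rng)
        self.aspp = DDSCASPP(self.backbone.out_channels, self.config, rng)
        self.cbam_deep = CBAM(self.config.aspp_out, rng,
                              reduction=self.config.cbam_reduction)
        self.decoder = Decoder(self.backbone.shallow_channels, self.config, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2:]
        shallow, deep = self.backbone(x)
        enc = self.cbam_deep(self.aspp(deep))
        return self.decoder(enc, shallow, (h, w))

    # -- inference helpers ------------------------------------------------
    @staticmethod
    def normalize(images: np.ndarray) -> np.ndarray:
        """HWC/NHWC uint8 or float images -> NCHW float64 in [-1, 1]."""
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.max() > 1.5:
            arr = arr / 127.5 - 1.0
        return arr.transpose(0, 3, 1, 2)

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        logits = self.forward(Tensor(self.normalize(images))).data
        self.train(was_training)
        return logits

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel argmax class map; ties resolve to the lowest class."""
        logits = self.predict_logits(image)
        labels = logits.argmax(axis=1).astype(np.uint8)
        return labels[0] if np.asarray(image).ndim == 3 else labels


def segment(image: np.ndarray, weights: dict | None = None,
            config: ModelConfig | None = None, seed: int = 42) -> np.ndarray:
    """Build a model (optionally loading ``weights``) and segment one image."""
    model = SDCDeepLab(config, seed=seed)
    if weights is not None:
        model.load_state_dict(weights)
    return model.segment(image)
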