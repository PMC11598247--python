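"""The segmentation/classification network.

One attention-enhanced residual encoder is shared by three structurally
identical decoder branches (nuclear probability, HV-distance regression,
nuclear classification).  Each branch emits a *coarse* prediction map and a
compact encoder–decoder refinement head (ARRM) adds a residual correction to
produce the *refined* map; both are supervised during training.

Encoder: a ResNet-50-style stack of bottleneck units whose stem keeps full
resolution (7x7 conv, stride 1, no initial pooling); stages 2–4 halve the
spatial size; every stage ends with a channel-then-spatial attention block
(CBAM-style).  Decoder: three x2 nearest-neighbour upsamplings with dense
blocks of 8 and 4 dense units after the first two, merging encoder skips by
elementwise addition (1x1 projection when channel counts differ).

Geometry: in ``same`` padding mode outputs match the input size (inputs must
be divisible by 8); an optional centre ``output_crop`` reproduces e.g. the
256 -> 164 contract.  In ``valid`` mode the published 270 -> 80 contract is
realized as same-padding interior computation followed by a centre crop of
``valid_margin`` (190) pixels total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, concat
from .nn.layers import (
    AttentionBlock,
    BatchNorm2d,
    ChannelAttention,
    Conv2d,
    Module,
    ReLU,
    Sequential,
)
from .nn.autograd import maxpool2x2, upsample_nearest2x
from .types import ModelConfig

__all__ = [
    "BranchOutputs",
    "AERNet",
    "build_encoder",
    "build_decoder_branch",
    "build_arrm",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class BranchOutputs:
    """Coarse and refined maps of the three branches (NCHW Tensors)."""

    prob_coarse: Tensor
    prob_refined: Tensor
    hv_coarse: Tensor
    hv_refined: Tensor
    class_coarse: Tensor
    class_refined: Tensor

    def spatial_size(self) -> tuple[int, int]:
        return self.prob_coarse.shape[2], self.prob_coarse.shape[3]


class BottleneckUnit(Module):
    """1x1 -> 3x3 -> 1x1 residual unit with projection shortcut on change."""

    def __init__(self, c_in, c_inner, c_out, rng, stride=1):
        self.conv1 = Conv2d(c_in, c_inner, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(c_inner)
        self.conv2 = Conv2d(c_inner, c_inner, 3, rng, stride=stride, bias=False)
        self.bn2 = BatchNorm2d(c_inner)
        self.conv3 = Conv2d(c_inner, c_out, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, rng, stride=stride, bias=False)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return (out + shortcut).relu()


class EncoderStage(Module):
    """n residual units (first may downsample) closed by an attention block."""

    def __init__(self, c_in, c_inner, c_out, n_units, rng, stride, reduction):
        units = [BottleneckUnit(c_in, c_inner, c_out, rng, stride=stride)]
        for _ in range(n_units - 1):
            units.append(BottleneckUnit(c_out, c_inner, c_out, rng))
        self.units = units
        self.attention = AttentionBlock(c_out, rng, reduction)

    def forward(self, x):
        for unit in self.units:
            x = unit(x)
        return self.attention(x)


class Encoder(Module):
    """Stride-1 stem plus four attention-closed residual stages.

    Exposes the four per-stage feature maps for decoder skips; stage 1 keeps
    full resolution, stages 2-4 downsample x2 each.
    """

    def __init__(self, config: ModelConfig, rng):
        w = config.base_width
        depths = config.residual_units_per_stage
        red = config.attention_reduction
        self.stem_conv = Conv2d(3, w, 7, rng, bias=False)
        self.stem_bn = BatchNorm2d(w)
        self.stage1 = EncoderStage(w, w, 4 * w, depths[0], rng, 1, red)
        self.stage2 = EncoderStage(4 * w, 2 * w, 8 * w, depths[1], rng, 2, red)
        self.stage3 = EncoderStage(8 * w, 4 * w, 16 * w, depths[2], rng, 2, red)
        self.stage4 = EncoderStage(16 * w, 8 * w, 32 * w, depths[3], rng, 2, red)
        self.stage_channels = (4 * w, 8 * w, 16 * w, 32 * w)

    def forward(self, x) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        x = self.stem_bn(self.stem_conv(x)).relu()
        e1 = self.stage1(x)
        e2 = self.stage2(e1)
        e3 = self.stage3(e2)
        e4 = self.stage4(e3)
        return e1, e2, e3, e4


class DenseUnit(Module):
    """Preactivated 1x1 (4g) -> 3x3 (g) unit with concatenative growth."""

    def __init__(self, c_in, growth, rng):
        self.bn1 = BatchNorm2d(c_in)
        self.conv1 = Conv2d(c_in, 4 * growth, 1, rng, bias=False)
        self.bn2 = BatchNorm2d(4 * growth)
        self.conv2 = Conv2d(4 * growth, growth, 3, rng, bias=False)

    def forward(self, x):
        out = self.conv1(self.bn1(x).relu())
        out = self.conv2(self.bn2(out).relu())
        return concat([x, out], axis=1)


class DenseBlock(Module):
    def __init__(self, c_in, n_units, growth, rng):
        units = []
        c = c_in
        for _ in range(n_units):
            units.append(DenseUnit(c, growth, rng))
            c += growth
        self.units = units
        self.out_channels = c

    def forward(self, x):
        for unit in self.units:
            x = unit(x)
        return x


class SkipAdd(Module):
    """Elementwise-add an encoder skip, 1x1-projecting it on channel mismatch."""

    def __init__(self, c_decoder, c_skip, rng):
        self.proj = (
            Conv2d(c_skip, c_decoder, 1, rng, bias=False)
            if c_skip != c_decoder
            else None
        )

    def forward(self, x, skip):
        if self.proj is not None:
            skip = self.proj(skip)
        return x + skip


def _crop_to(t: Tensor, h: int, w: int) -> Tensor:
    """Top-left crop to (h, w); aligns with ceil-mode downsampling padding."""
    if t.shape[2] == h and t.shape[3] == w:
        return t
    return t[:, :, :h, :w]


def _center_crop(t: Tensor, h: int, w: int) -> Tensor:
    th, tw = t.shape[2], t.shape[3]
    top = (th - h) // 2
    left = (tw - w) // 2
    return t[:, :, top : top + h, left : left + w]


class DecoderBranch(Module):
    """Three x2 upsampling stages with dense blocks and additive skips."""

    def __init__(self, config: ModelConfig, out_channels: int, rng):
        w = config.base_width
        g = config.dense_growth
        c1, c2, c3, c4 = (4 * w, 8 * w, 16 * w, 32 * w)
        self.reduce1 = Conv2d(c4, c3, 1, rng, bias=False)
        self.skip3 = SkipAdd(c3, c3, rng)
        self.dense1 = DenseBlock(c3, 8, g, rng)
        self.compress1 = Conv2d(self.dense1.out_channels, c2, 1, rng, bias=False)
        self.skip2 = SkipAdd(c2, c2, rng)
        self.dense2 = DenseBlock(c2, 4, g, rng)
        self.compress2 = Conv2d(self.dense2.out_channels, c1, 1, rng, bias=False)
        self.skip1 = SkipAdd(c1, c1, rng)
        self.final_conv = Conv2d(c1, 2 * w, 3, rng, bias=False)
        self.final_bn = BatchNorm2d(2 * w)
        self.head = Conv2d(2 * w, out_channels, 1, rng)
        self.out_channels = out_channels

    def forward(self, e1, e2, e3, e4):
        x = upsample_nearest2x(e4)
        x = _crop_to(x, e3.shape[2], e3.shape[3])
        x = self.skip3(self.reduce1(x), e3)
        x = self.compress1(self.dense1(x))
        x = upsample_nearest2x(x)
        x = _crop_to(x, e2.shape[2], e2.shape[3])
        x = self.skip2(x, e2)
        x = self.compress2(self.dense2(x))
        x = upsample_nearest2x(x)
        x = _crop_to(x, e1.shape[2], e1.shape[3])
        x = self.skip1(x, e1)
        x = self.final_bn(self.final_conv(x)).relu()
        return self.head(x)


class ChannelAttentionConv(Module):
    """3x3 conv -> BN -> ReLU -> channel attention (refinement-head unit)."""

    def __init__(self, c_in, c_out, rng, reduction):
        self.conv = Conv2d(c_in, c_out, 3, rng, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.attention = ChannelAttention(c_out, rng, reduction)

    def forward(self, x):
        return self.attention(self.bn(self.conv(x)).relu())


class ARRM(Module):
    """Attention-enhanced residual refinement head.

    A compact encoder–decoder over a branch's coarse prediction map: entry
    conv, N pooling stages of channel-attention convs, a channel-attention
    bridge, N upsampling conv stages and an exit conv back to the branch's
    channel count.  The output is a residual added to the coarse map.
    """

    def __init__(self, channels: int, config: ModelConfig, rng):
        c = config.arrm_width
        red = config.attention_reduction
        self.n_stages = config.arrm_pool_stages
        self.entry = Conv2d(channels, c, 3, rng, bias=False)
        self.enc_stages = [
            ChannelAttentionConv(c, c, rng, red) for _ in range(self.n_stages)
        ]
        self.bridge = ChannelAttentionConv(c, c, rng, red)
        self.dec_convs = [
            Sequential(Conv2d(c, c, 3, rng, bias=False), BatchNorm2d(c), ReLU())
            for _ in range(self.n_stages)
        ]
        self.exit = Conv2d(c, channels, 3, rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        factor = 2**self.n_stages
        if h % factor or w % factor:
            raise ValueError(
                f"ARRM with {self.n_stages} pooling stages needs spatial size "
                f"divisible by {factor}, got {h}x{w}"
            )
        out = self.entry(x)
        for stage in self.enc_stages:
            out = maxpool2x2(stage(out))
        out = self.bridge(out)
        for conv in self.dec_convs:
            out = conv(upsample_nearest2x(out))
        return self.exit(out)


class AERNet(Module):
    """Full model: shared encoder, three decoder branches, one ARRM each."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.num_classes
        self.encoder = Encoder(config, rng)
        self.prob_branch = DecoderBranch(config, 2, rng)
        self.hv_branch = DecoderBranch(config, 2, rng)
        self.class_branch = DecoderBranch(config, k + 1, rng)
        # ARRMs built last so the coarse path's weights do not depend on them
        if config.use_arrm:
            self.prob_arrm = ARRM(2, config, rng)
            self.hv_arrm = ARRM(2, config, rng)
            self.class_arrm = ARRM(k + 1, config, rng)
        else:
            self.prob_arrm = self.hv_arrm = self.class_arrm = None

    def _check_input(self, x: Tensor):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("input must be N x 3 x H x W")
        h, w = x.shape[2], x.shape[3]
        if self.config.padding_mode == "same" and (h % 8 or w % 8):
            raise ValueError(
                f"same-padding mode needs input sizes divisible by 8, got {h}x{w}"
            )
        if self.config.padding_mode == "valid":
            m = self.config.valid_margin
            if h <= m or w <= m:
                raise ValueError(
                    f"valid mode needs input larger than the {m}-px margin"
                )

    def _output_geometry(self, h: int, w: int) -> tuple[int, int]:
        if self.config.padding_mode == "valid":
            m = self.config.valid_margin
            return h - m, w - m
        if self.config.output_crop is not None:
            c = self.config.output_crop
            return c, c
        return h, w

    def forward(self, x: Tensor) -> BranchOutputs:
        if not self.training:
            # inference needs no graph; lets activations free eagerly
            from .nn.autograd import no_grad

            with no_grad():
                return self._forward_impl(x)
        return self._forward_impl(x)

    def _forward_impl(self, x: Tensor) -> BranchOutputs:
        self._check_input(x)
        oh, ow = self._output_geometry(x.shape[2], x.shape[3])
        e1, e2, e3, e4 = self.encoder(x)
        coarse = [
            _center_crop(branch(e1, e2, e3, e4), oh, ow)
            for branch in (self.prob_branch, self.hv_branch, self.class_branch)
        ]
        arrms = (self.prob_arrm, self.hv_arrm, self.class_arrm)
        refined = [
            c if a is None else c + a(c) for c, a in zip(coarse, arrms)
        ]
        return BranchOutputs(
            prob_coarse=coarse[0],
            prob_refined=refined[0],
            hv_coarse=coarse[1],
            hv_refined=refined[1],
            class_coarse=coarse[2],
            class_refined=refined[2],
        )


def build_encoder(config: ModelConfig) -> Encoder:
    return Encoder(config, np.random.default_rng(config.seed))


def build_decoder_branch(config: ModelConfig, out_channels: int) -> DecoderBranch:
    return DecoderBranch(config, out_channels, np.random.default_rng(config.seed))


def build_arrm(config: ModelConfig, channels: int) -> ARRM:
    return ARRM(channels, config, np.random.default_rng(config.seed))


def load_backbone_weights(model: AERNet, path) -> int:
    """Hook: load encoder-only weights from a compatible checkpoint archive.

    Keys prefixed ``encoder.`` are copied where shapes match; returns the
    number of arrays loaded.  Intended for warm-starting the encoder from a
    pretrained backbone; no weights ship with the package.
    """
    loaded = 0
    with np.load(path) as archive:
        state = model.state_dict()
        for key in archive.files:
            if key.startswith("encoder.") and key in state:
                if archive[key].shape == state[key].shape:
                    state[key] = archive[key]
                    loaded += 1
    model.load_state_dict(state)
    return loaded


def save_checkpoint(model: AERNet, path) -> None:
    """Single-file archive: weights plus the embedded config JSON."""
    state = model.state_dict()
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path) -> AERNet:
    with np.load(path) as archive:
        config = ModelConfig.from_dict(
            json.loads(archive["__config__"].tobytes().decode())
        )
        model = AERNet(config)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    return model
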