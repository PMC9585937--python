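"""The N-Net: dense-block encoder, GHDC skip blocks, decoder, and wiring.

The network is an encoder-decoder with four stages on each side.  The encoder
is DenseNet-121-flavoured: a 7x7 stem (conv stride 2 + 7x7 max-pool stride 2,
total /4), then three dense stages of 6/12/24 dense layers whose outputs are
tapped at 64/256/512/1024 channels, each stage beginning with a downsampling
transition so consecutive taps halve in resolution.  Four GHDC blocks bridge
encoder and decoder: block ``i`` reads the concatenation of encoder tap ``i``
and the bilinearly-upsampled output of block ``i+1``, extracts multi-scale
context through parallel prefix-branches of a gridding-free dilated cascade,
and fuses them with a 3x3 convolution.  Decoder stage ``i`` reads the
point-wise sum of GHDC block ``i``'s output and decoder stage ``i+1``'s
output; the final head produces a per-pixel foreground probability at input
resolution.

Any GHDC block can be replaced by a plain 1x1 projection skip ("ablation
mode"); replacing all four gives the plain encoder-decoder baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .design import CascadeSpec, receptive_field, validate_cascade
from .nn import Tensor, concat

__all__ = [
    "EncoderSpec",
    "GHDCBlockSpec",
    "DecoderSpec",
    "NNetSpec",
    "ShapeTrace",
    "TABLE_CASCADES",
    "default_nnet_spec",
    "build_ghdc_block",
    "build_transition",
    "assemble_nnet",
    "count_parameters",
    "shape_infer",
    "NNet",
]

# Default skip-block cascades, from block 1 (highest resolution) to block 4.
TABLE_CASCADES: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    1: ((1, 2, 5, 7, 9), (3, 3, 3, 5, 5)),  # F = 81
    2: ((1, 2, 5, 7), (3, 3, 3, 5)),        # F = 45
    3: ((1, 2, 5), (3, 3, 3)),              # F = 17
    4: ((1, 2), (3, 3)),                    # F = 7
}


@dataclass(frozen=True)
class EncoderSpec:
    """Dense encoder: stem channels, growth rate, 6/12/24 dense layers, 4 taps."""

    stem_channels: int = 64
    growth_rate: int = 32
    dense_layers: tuple[int, int, int] = (6, 12, 24)
    pretrained: bool = False

    @property
    def tap_channels(self) -> tuple[int, int, int, int]:
        t1 = self.stem_channels
        t2 = t1 + self.dense_layers[0] * self.growth_rate
        t3 = t2 // 2 + self.dense_layers[1] * self.growth_rate
        t4 = t3 // 2 + self.dense_layers[2] * self.growth_rate
        return (t1, t2, t3, t4)

    def __post_init__(self) -> None:
        if self.dense_layers != (6, 12, 24):
            raise ValueError(f"dense layer counts must be (6, 12, 24), got {self.dense_layers}")
        taps = self.tap_channels
        if not all(a < b for a, b in zip(taps, taps[1:])):
            raise ValueError(f"tap channels must be strictly increasing, got {taps}")


@dataclass(frozen=True)
class GHDCBlockSpec:
    """One skip block: gridding-free cascade plus channel bookkeeping."""

    cascade: CascadeSpec
    in_channels: int
    out_channels: int
    branch_width: int

    def __post_init__(self) -> None:
        if min(self.in_channels, self.out_channels, self.branch_width) < 1:
            raise ValueError("channel counts must be positive")
        profile = validate_cascade(self.cascade)
        if not profile.valid:
            raise ValueError(f"GHDC block cascade is not gridding-free:\n{profile.diagnostic}")


@dataclass(frozen=True)
class DecoderSpec:
    """Decoder stage widths, listed from stage 4 down to stage 1.

    Stages 4..2 follow Conv(1x1)-BN-ReLU-TransposeConv(3x3, stride 2)-BN-
    Conv(1x1) with bottleneck width ``out_channels // 2``; stage 1 is two 3x3
    convolutions followed by bilinear upsampling to input resolution.
    """

    out_channels: tuple[int, int, int, int] = (512, 256, 64, 1)

    def __post_init__(self) -> None:
        if self.out_channels[3] != 1:
            raise ValueError("the final decoder stage must output 1 channel")


@dataclass(frozen=True)
class NNetSpec:
    """Complete architecture description; ``active_blocks`` enables ablations."""

    encoder: EncoderSpec
    ghdc_blocks: tuple[GHDCBlockSpec, GHDCBlockSpec, GHDCBlockSpec, GHDCBlockSpec]
    decoder: DecoderSpec
    input_size: tuple[int, int] = (256, 320)
    active_blocks: frozenset[int] = frozenset({1, 2, 3, 4})

    def __post_init__(self) -> None:
        _check_input_size(self.input_size)
        if not self.active_blocks <= {1, 2, 3, 4}:
            raise ValueError(f"active_blocks must be a subset of {{1,2,3,4}}")
        taps = self.encoder.tap_channels
        # decoder.out_channels is (stage4, stage3, stage2, stage1); point-wise
        # addition requires decoder stage i+1 to match GHDC block i's output
        d4, d3, d2, _ = self.decoder.out_channels
        expect = (taps[2], taps[1], taps[0])  # GHDC3, GHDC2, GHDC1 out channels
        if (d4, d3, d2) != expect:
            raise ValueError(
                f"decoder stage outputs {(d4, d3, d2)} must match GHDC block "
                f"3/2/1 outputs {expect} for point-wise addition"
            )


def _check_input_size(size: tuple[int, int]) -> None:
    h, w = size
    if h % 32 or w % 32 or h < 32 or w < 32:
        raise ValueError(
            f"input size {h}x{w} unsupported: the encoder downsamples by 32 "
            f"(stem /4 then three /2), so both sides must be multiples of 32"
        )


def default_nnet_spec(
    input_size: tuple[int, int] = (256, 320),
    width_divisor: int = 1,
    active_blocks=(1, 2, 3, 4),
) -> NNetSpec:
    """The default configuration: taps 64/256/512/1024, the four standard
    cascades, decoder widths 512/256/64/1.

    ``width_divisor`` scales every channel count down (1, 2, 4 or 8) for
    desk-scale experiments with identical topology and cascades.
    """
    d = width_divisor
    if d not in (1, 2, 4, 8):
        raise ValueError("width_divisor must be one of 1, 2, 4, 8")
    encoder = EncoderSpec(stem_channels=64 // d, growth_rate=32 // d)
    taps = encoder.tap_channels
    blocks = []
    for i in (1, 2, 3, 4):
        rates, kernels = TABLE_CASCADES[i]
        out_c = taps[i - 1]
        in_c = taps[3] if i == 4 else 2 * taps[i - 1]
        blocks.append(
            GHDCBlockSpec(
                cascade=CascadeSpec.from_lists(rates, kernels),
                in_channels=in_c,
                out_channels=out_c,
                branch_width=max(out_c // 4, 4),
            )
        )
    decoder = DecoderSpec(out_channels=(taps[2], taps[1], taps[0], 1))
    return NNetSpec(
        encoder=encoder,
        ghdc_blocks=tuple(blocks),
        decoder=decoder,
        input_size=input_size,
        active_blocks=frozenset(active_blocks),
    )


# ---------------------------------------------------------------------------
# modules


def _conv_bn_relu(in_c, out_c, k, rng, dilation=1) -> nn.Sequential:
    pad = dilation * (k - 1) // 2
    return nn.Sequential(
        nn.Conv2d(in_c, out_c, k, rng=rng, padding=pad, dilation=dilation, bias=False),
        nn.BatchNorm2d(out_c),
        nn.ReLU(),
    )


class _DenseLayer(nn.Module):
    def __init__(self, in_c: int, growth: int, rng):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_c)
        self.relu = nn.ReLU()
        self.conv1 = nn.Conv2d(in_c, 4 * growth, 1, rng=rng, bias=False)
        self.bn2 = nn.BatchNorm2d(4 * growth)
        self.conv2 = nn.Conv2d(4 * growth, growth, 3, rng=rng, padding=1, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(self.relu(self.bn1(x)))
        y = self.conv2(self.relu(self.bn2(y)))
        return concat([x, y], axis=1)


class _DenseBlock(nn.Module):
    def __init__(self, in_c: int, num_layers: int, growth: int, rng):
        super().__init__()
        layers = []
        c = in_c
        for _ in range(num_layers):
            layers.append(_DenseLayer(c, growth, rng))
            c += growth
        self.block = nn.Sequential(*layers)
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class _Encoder(nn.Module):
    """Stem + three dense stages; returns the four taps."""

    def __init__(self, spec: EncoderSpec, rng):
        super().__init__()
        t1, t2, t3, t4 = spec.tap_channels
        g = spec.growth_rate
        self.stem = nn.Sequential(
            nn.Conv2d(3, t1, 7, rng=rng, stride=2, padding=3, bias=False),
            nn.BatchNorm2d(t1),
            nn.ReLU(),
            nn.MaxPool2d(7, stride=2, padding=3),
        )
        self.stage2 = nn.Sequential(nn.AvgPool2d(), _DenseBlock(t1, spec.dense_layers[0], g, rng))
        self.stage3 = nn.Sequential(
            nn.BatchNorm2d(t2),
            nn.ReLU(),
            nn.Conv2d(t2, t2 // 2, 1, rng=rng, bias=False),
            nn.AvgPool2d(),
            _DenseBlock(t2 // 2, spec.dense_layers[1], g, rng),
        )
        self.stage4 = nn.Sequential(
            nn.BatchNorm2d(t3),
            nn.ReLU(),
            nn.Conv2d(t3, t3 // 2, 1, rng=rng, bias=False),
            nn.AvgPool2d(),
            _DenseBlock(t3 // 2, spec.dense_layers[2], g, rng),
        )

    def forward(self, x: Tensor) -> list[Tensor]:
        e1 = self.stem(x)
        e2 = self.stage2(e1)
        e3 = self.stage3(e2)
        e4 = self.stage4(e3)
        return [e1, e2, e3, e4]


class GHDCBlock(nn.Module):
    """Parallel prefix-branches of a gridding-free cascade, concat + 3x3 fuse.

    Branch ``j`` applies layers 1..j of the cascade (each a dilated conv +
    BN + ReLU at ``branch_width`` channels, entered through a 1x1 reduction),
    so the block sees receptive fields of every prefix simultaneously.
    """

    def __init__(self, spec: GHDCBlockSpec, rng):
        super().__init__()
        self.spec = spec
        L = len(spec.cascade)
        bw = spec.branch_width
        branches = []
        for j in range(1, L + 1):
            stages = [_conv_bn_relu(spec.in_channels, bw, 1, rng)]
            for layer in spec.cascade.layers[:j]:
                stages.append(
                    _conv_bn_relu(bw, bw, layer.kernel_size, rng, dilation=layer.dilation_rate)
                )
            branches.append(nn.Sequential(*stages))
        self.branches = nn.Sequential(*branches)
        self.fuse = _conv_bn_relu(L * bw, spec.out_channels, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = [branch(x) for branch in self.branches.layers]
        return self.fuse(concat(feats, axis=1))


def build_ghdc_block(spec: GHDCBlockSpec, rng=None) -> GHDCBlock:
    """Construct a GHDC block; an invalid (gridding) cascade is rejected by the spec type."""
    return GHDCBlock(spec, rng if rng is not None else np.random.default_rng(0))


class _PlainSkip(nn.Module):
    """Ablation replacement for a GHDC block: 1x1 projection + BN + ReLU."""

    def __init__(self, in_c: int, out_c: int, rng):
        super().__init__()
        self.proj = _conv_bn_relu(in_c, out_c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(x)


def build_transition(in_channels: int, out_channels: int, rng=None) -> nn.Sequential:
    """Skip-path hand-off: bilinear x2 upsampling then Conv(3x3)-BN-ReLU.

    Odd spatial inputs are legal (H doubles exactly under the half-pixel
    bilinear convention).
    """
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    return nn.Sequential(nn.UpsampleBilinear(2), *(_conv_bn_relu(in_channels, out_channels, 3, rng).layers))


class _DecoderStage(nn.Module):
    """Conv(1x1)-BN-ReLU -> TransposeConv(3x3, stride 2)-BN -> Conv(1x1)."""

    def __init__(self, in_c: int, out_c: int, rng):
        super().__init__()
        mid = max(out_c // 2, 4)
        self.reduce = nn.Sequential(
            nn.Conv2d(in_c, mid, 1, rng=rng, bias=False), nn.BatchNorm2d(mid), nn.ReLU()
        )
        self.up = nn.Sequential(
            nn.ConvTranspose2d(mid, mid, 3, rng=rng, stride=2, padding=1, output_padding=1, bias=False),
            nn.BatchNorm2d(mid),
        )
        self.project = nn.Conv2d(mid, out_c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.up(self.reduce(x)))


class _DecoderHead(nn.Module):
    """Stage 1: two 3x3 convolutions then bilinear upsampling to input resolution."""

    def __init__(self, in_c: int, rng):
        super().__init__()
        mid = max(in_c // 2, 4)
        self.conv1 = _conv_bn_relu(in_c, mid, 3, rng)
        self.conv2 = nn.Conv2d(mid, 1, 3, rng=rng, padding=1)
        self.up = nn.UpsampleBilinear(4)

    def forward(self, x: Tensor) -> Tensor:
        return self.up(self.conv2(self.conv1(x)))


class NNet(nn.Module):
    """The assembled segmentation network; ``forward`` yields probabilities in [0,1]."""

    def __init__(self, spec: NNetSpec, rng):
        super().__init__()
        self.spec = spec
        taps = spec.encoder.tap_channels
        self.encoder = _Encoder(spec.encoder, rng)
        skips = []
        for i in (1, 2, 3, 4):
            bspec = spec.ghdc_blocks[i - 1]
            if i in spec.active_blocks:
                skips.append(GHDCBlock(bspec, rng))
            else:
                skips.append(_PlainSkip(bspec.in_channels, bspec.out_channels, rng))
        self.skips = nn.Sequential(*skips)
        self.trans4 = build_transition(taps[3], taps[2], rng)
        self.trans3 = build_transition(taps[2], taps[1], rng)
        self.trans2 = build_transition(taps[1], taps[0], rng)
        d4, d3, d2, _ = spec.decoder.out_channels
        self.dec4 = _DecoderStage(taps[3], d4, rng)
        self.dec3 = _DecoderStage(d4, d3, rng)
        self.dec2 = _DecoderStage(d3, d2, rng)
        self.dec1 = _DecoderHead(d2, rng)

    def _add(self, a: Tensor, b: Tensor, edge: str) -> Tensor:
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch at {edge}: {a.shape} vs {b.shape}")
        return a + b

    def _cat(self, a: Tensor, b: Tensor, edge: str) -> Tensor:
        if a.shape[2:] != b.shape[2:]:
            raise ValueError(f"spatial mismatch at {edge}: {a.shape} vs {b.shape}")
        return concat([a, b], axis=1)

    def forward_logits(self, x: Tensor) -> Tensor:
        e1, e2, e3, e4 = self.encoder(x)
        block1, block2, block3, block4 = self.skips.layers
        g4 = block4(e4)
        g3 = block3(self._cat(e3, self.trans4(g4), "encoder3 ++ transition(GHDC4)"))
        g2 = block2(self._cat(e2, self.trans3(g3), "encoder2 ++ transition(GHDC3)"))
        g1 = block1(self._cat(e1, self.trans2(g2), "encoder1 ++ transition(GHDC2)"))
        d4 = self.dec4(g4)
        d3 = self.dec3(self._add(g3, d4, "GHDC3 + decoder4"))
        d2 = self.dec2(self._add(g2, d3, "GHDC2 + decoder3"))
        return self.dec1(self._add(g1, d2, "GHDC1 + decoder2"))

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()


def assemble_nnet(spec: NNetSpec, seed: int = 0) -> NNet:
    """Build the network with seeded He initialization; fails loudly on any
    inconsistent wiring (the spec types validate cascades and channel matching,
    and a symbolic shape pass checks the rest before weights are used)."""
    shape_infer(spec, spec.input_size)  # raises with the offending edge named
    return NNet(spec, np.random.default_rng(seed))


def count_parameters(network: nn.Module) -> int:
    """Total trainable scalar parameter count."""
    return int(sum(p.data.size for p in network.parameters()))


@dataclass(frozen=True)
class ShapeTrace:
    """(channels, height, width) records for every named node of the network."""

    records: tuple[tuple[str, tuple[int, int, int]], ...]

    def __getitem__(self, name: str) -> tuple[int, int, int]:
        for n, shape in self.records:
            if n == name:
                return shape
        raise KeyError(name)

    def __str__(self) -> str:
        width = max(len(n) for n, _ in self.records)
        return "\n".join(
            f"{n:<{width}}  {c:>5} x {h:>4} x {w:>4}" for n, (c, h, w) in self.records
        )


def shape_infer(spec: NNetSpec, input_size: tuple[int, int]) -> ShapeTrace:
    """Symbolic shape propagation through the whole graph, without weights."""
    _check_input_size(input_size)
    h, w = input_size
    taps = spec.encoder.tap_channels
    rec: list[tuple[str, tuple[int, int, int]]] = [("input", (3, h, w))]
    eh, ew = h // 4, w // 4
    enc_shapes = []
    for i in (1, 2, 3, 4):
        enc_shapes.append((taps[i - 1], eh, ew))
        rec.append((f"encoder{i}", enc_shapes[-1]))
        eh, ew = eh // 2, ew // 2
    ghdc_shapes: dict[int, tuple[int, int, int]] = {}
    for i in (4, 3, 2, 1):
        bspec = spec.ghdc_blocks[i - 1]
        c_e, hh, ww = enc_shapes[i - 1]
        if i == 4:
            in_c = c_e
        else:
            c_up, h_up, w_up = ghdc_shapes[i + 1]
            th, tw = h_up * 2, w_up * 2
            rec.append((f"transition{i + 1}->{i}", (taps[i - 1], th, tw)))
            if (th, tw) != (hh, ww):
                raise ValueError(
                    f"shape mismatch at encoder{i} ++ transition(GHDC{i + 1}): "
                    f"{(hh, ww)} vs {(th, tw)}"
                )
            in_c = c_e + taps[i - 1]
        if in_c != bspec.in_channels:
            raise ValueError(
                f"GHDC block {i} expects {bspec.in_channels} input channels but "
                f"receives {in_c}"
            )
        ghdc_shapes[i] = (bspec.out_channels, hh, ww)
        rec.append((f"ghdc{i}", ghdc_shapes[i]))
    d4, d3, d2, _ = spec.decoder.out_channels
    prev = None
    for i, out_c in zip((4, 3, 2), (d4, d3, d2)):
        c_g, hh, ww = ghdc_shapes[i]
        if prev is not None and prev != (c_g, hh, ww):
            raise ValueError(
                f"shape mismatch at GHDC{i} + decoder{i + 1}: {(c_g, hh, ww)} vs {prev}"
            )
        prev = (out_c, hh * 2, ww * 2)
        rec.append((f"decoder{i}", prev))
    if prev != ghdc_shapes[1]:
        raise ValueError(f"shape mismatch at GHDC1 + decoder2: {ghdc_shapes[1]} vs {prev}")
    rec.append(("decoder1", (1, h, w)))
    rec.append(("output", (1, h, w)))
    return ShapeTrace(records=tuple(rec))
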