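"""Generator and discriminator architectures.

The generator is a five-scale encoder-decoder with *full-scale* skip
fusion: every decoder step receives 32-channel projections of all five
scales (encoder maps resized down, deeper decoder maps resized up), so each
fusion convolution sees 5 x 32 = 160 concatenated feature maps.
Downsampling is by strided 3^3 convolutions (no pooling) and upsampling by
trilinear interpolation followed by convolution, which avoids checkerboard
artefacts.  The final activation is tanh, so outputs live in (-1, 1) on the
normalised dose scale.

The discriminator is a fully convolutional 3D patch classifier: five
kernel-4 layers with strides (2, 2, 2, 1, 1), giving every output logit a
70^3-voxel receptive field.

The default block plans (stem of three convolutions at width 32, encoder
widths 64/128/256/512 with two extra convolutions at each level except the
deepest, 1^3 skip projections, 160->80 fusion with an 80-wide head; and the
discriminator channel ladder 108/216/416/814) reproduce the recorded
trainable-parameter totals of 11.077 M (generator, 7-channel input) and
29.026 M (discriminator, 8-channel input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Var


def _scaled(width: int, mult: float) -> int:
    return max(1, int(round(width * mult)))


@dataclass
class GeneratorSpec:
    """Block plan of the full-scale fusion generator (see module docstring)."""

    in_channels: int = 7  # scheme A at inference: CT + 6 structure channels
    stem_width: int = 32
    stem_convs: int = 3
    encoder_widths: tuple[int, ...] = (64, 128, 256, 512)
    #: extra stride-1 convolutions after each downsampling conv
    encoder_convs: tuple[int, ...] = (2, 2, 2, 0)
    skip_width: int = 32
    scales: int = 5
    decoder_width: int = 80
    branch_kernel: int = 1
    head_width: int = 80
    width_mult: float = 1.0

    def scaled(self) -> "GeneratorSpec":
        m = self.width_mult
        if m == 1.0:
            return self
        return GeneratorSpec(
            in_channels=self.in_channels,
            stem_width=_scaled(self.stem_width, m),
            stem_convs=self.stem_convs,
            encoder_widths=tuple(_scaled(w, m) for w in self.encoder_widths),
            encoder_convs=self.encoder_convs,
            skip_width=_scaled(self.skip_width, m),
            scales=self.scales,
            decoder_width=_scaled(self.decoder_width, m),
            branch_kernel=self.branch_kernel,
            head_width=_scaled(self.head_width, m),
            width_mult=1.0,
        )

    @property
    def fused_width(self) -> int:
        s = self.scaled()
        return s.skip_width * s.scales

    def to_dict(self):
        return asdict(self)


@dataclass
class DiscriminatorSpec:
    """Layer plan of the 3D patch discriminator."""

    in_channels: int = 8  # scheme A stack including the dose channel
    widths: tuple[int, ...] = (108, 216, 416, 814)
    kernel: int = 4
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    leaky_slope: float = 0.2
    width_mult: float = 1.0

    def scaled(self) -> "DiscriminatorSpec":
        m = self.width_mult
        if m == 1.0:
            return self
        return DiscriminatorSpec(
            in_channels=self.in_channels,
            widths=tuple(_scaled(w, m) for w in self.widths),
            kernel=self.kernel,
            strides=self.strides,
            leaky_slope=self.leaky_slope,
            width_mult=1.0,
        )

    def to_dict(self):
        return asdict(self)


def receptive_field_extent(kernels, strides) -> int:
    """Per-axis receptive field: RF = 1 + sum_i (k_i - 1) * prod_{j<i} s_j."""
    rf, jump = 1, 1
    for k, s in zip(kernels, strides):
        rf += (k - 1) * jump
        jump *= s
    return rf


def count_parameters(module: nn.Module) -> int:
    """Total number of trainable scalars in a module."""
    return int(sum(p.data.size for p in module.parameters()))


class Generator(nn.Module):
    """Full-scale feature-fusion encoder-decoder dose generator."""

    def __init__(self, spec: GeneratorSpec | None = None, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.spec = (spec or GeneratorSpec()).scaled()
        s = self.spec
        rng = np.random.default_rng(seed)
        kw = dict(rng=rng, dtype=dtype)

        stem = [nn.ConvBlock(s.in_channels, s.stem_width, 3, **kw)]
        stem += [
            nn.ConvBlock(s.stem_width, s.stem_width, 3, **kw)
            for _ in range(s.stem_convs - 1)
        ]
        self.stem = stem

        self.enc_widths = [s.stem_width] + list(s.encoder_widths)
        self.down, self.enc_extra = [], []
        prev = s.stem_width
        for w, n_extra in zip(s.encoder_widths, s.encoder_convs):
            self.down.append(nn.ConvBlock(prev, w, 3, stride=2, **kw))
            self.enc_extra.append(
                [nn.ConvBlock(w, w, 3, **kw) for _ in range(n_extra)]
            )
            prev = w

        # decoder steps at scales 4, 3, 2, 1; each fuses `scales` branches
        self.branches, self.fuse = [], []
        for j in (4, 3, 2, 1):
            src_widths = self.enc_widths[:j]
            src_widths += [s.decoder_width] * (4 - j)
            src_widths += [self.enc_widths[-1]]
            self.branches.append(
                [nn.ConvBlock(sw, s.skip_width, s.branch_kernel, **kw)
                 for sw in src_widths]
            )
            self.fuse.append(
                nn.ConvBlock(s.skip_width * s.scales, s.decoder_width, 3, **kw)
            )
        self.head = nn.ConvBlock(s.decoder_width, s.head_width, 3, **kw)
        self.out = nn.Conv3d(s.head_width, 1, 3, bias=True, init_a=1.0, **kw)
        #: fused channel count observed at each decoder step of the last forward
        self.fusion_input_channels: list[int] = []

    def parameters(self):
        out = []
        for blk in self.stem:
            out += blk.parameters()
        for down, extras in zip(self.down, self.enc_extra):
            out += down.parameters()
            for blk in extras:
                out += blk.parameters()
        for branches, fuse in zip(self.branches, self.fuse):
            for blk in branches:
                out += blk.parameters()
            out += fuse.parameters()
        out += self.head.parameters() + self.out.parameters()
        return out

    def _check_input(self, x):
        spatial = x.shape[2:]
        for n in spatial:
            if n % 16:
                raise ValueError(
                    f"generator input sizes must be divisible by 16, got {spatial}"
                )

    @staticmethod
    def _resize(v: Var, from_scale: int, to_scale: int) -> Var:
        steps = to_scale - from_scale
        for _ in range(steps):
            v = nn.avgpool2(v)
        for _ in range(-steps):
            v = nn.upsample2_linear(v)
        return v

    def forward(self, x) -> Var:
        x = nn.as_var(x)
        self._check_input(x)
        h = x
        for blk in self.stem:
            h = blk(h)
        feats = {1: h}  # encoder features per scale
        for level, (down, extras) in enumerate(zip(self.down, self.enc_extra), start=2):
            h = down(h)
            for blk in extras:
                h = blk(h)
            feats[level] = h

        self.fusion_input_channels = []
        dec = {5: feats[5]}
        for step_idx, j in enumerate((4, 3, 2, 1)):
            sources = [(feats[k], k) for k in range(1, j + 1)]
            sources += [(dec[m], m) for m in range(j + 1, 5)]
            sources += [(feats[5], 5)]
            parts = []
            for blk, (src, k) in zip(self.branches[step_idx], sources):
                if k < j:
                    # shallow source: pool to the target scale, then project
                    parts.append(blk(self._resize(src, k, j)))
                else:
                    # deep source: project to skip width first, then upsample
                    # (cheaper, same parameters)
                    parts.append(self._resize(blk(src), k, j))
            fused = nn.concat(parts, axis=1)
            self.fusion_input_channels.append(fused.shape[1])
            dec[j] = self.fuse[step_idx](fused)
        y = self.head(dec[1])
        return nn.tanh(self.out(y))


class Discriminator(nn.Module):
    """3D patch classifier emitting a field of real/fake logits."""

    def __init__(self, spec: DiscriminatorSpec | None = None, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.spec = (spec or DiscriminatorSpec()).scaled()
        s = self.spec
        rng = np.random.default_rng(seed)
        k = s.kernel
        widths = list(s.widths)
        layers = [
            nn.ConvBlock(s.in_channels, widths[0], k, stride=s.strides[0], pad=1,
                         act="lrelu", norm=False, rng=rng, dtype=dtype)
        ]
        for i in range(1, len(widths)):
            layers.append(
                nn.ConvBlock(widths[i - 1], widths[i], k, stride=s.strides[i],
                             pad=1, act="lrelu", norm=True, rng=rng, dtype=dtype)
            )
        layers.append(
            nn.Conv3d(widths[-1], 1, k, stride=s.strides[-1], pad=1, bias=True,
                      rng=rng, init_a=1.0, dtype=dtype)
        )
        self.layers = layers

    def output_shape(self, spatial) -> tuple[int, ...]:
        """Logit-map spatial shape for an input of the given spatial size."""
        out = []
        for n in spatial:
            for s in self.spec.strides:
                n = (n + 2 - self.spec.kernel) // s + 1
                if n < 1:
                    raise ValueError(
                        f"input {spatial} too small for the discriminator "
                        "stride plan (empty logit map)"
                    )
            out.append(n)
        return tuple(out)

    def forward(self, x) -> Var:
        x = nn.as_var(x)
        self.output_shape(x.shape[2:])  # validates size
        for layer in self.layers:
            x = layer(x)
        return x


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0,
                    dtype=np.float32) -> Generator:
    return Generator(spec, seed=seed, dtype=dtype)


def build_discriminator(spec: DiscriminatorSpec | None = None, seed: int = 0,
                        dtype=np.float32) -> Discriminator:
    return Discriminator(spec, seed=seed, dtype=dtype)


#: generator input channels (dose channel excluded) per dataset scheme
GENERATOR_IN_CHANNELS = {"A": 7, "B": 2, "C": 1}
#: discriminator input channels (dose channel included) per dataset scheme
DISCRIMINATOR_IN_CHANNELS = {"A": 8, "B": 3, "C": 2}
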