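"""Builders for the three volumetric architectures used by the method.

* a 3D U-Net generator (three 2x down/upsampling stages, channel stack
  20-40 / 40-80 / 80-160 / 160-320 encoder and 160-160 / 80-80 / 40-40
  decoder, instance norm + ReLU, 1x1x1 tanh head).  In the multi-contrast
  configuration one encoder is shared by two independent decoders, with
  per-decoder skip connections, consuming T1w+T2w channel-wise concatenated
  (T1 first) and emitting both predicted contrasts;
* a patch discriminator (four stride-2 4x4x4 convolutions with 64, 128,
  256, 512 channels, LeakyReLU 0.2, instance norm on layers 2-4, and a
  stride-1 single-channel sigmoid head producing a score map);
* an encoder-style feature extractor for the perceptual loss (blocks
  32-64, 64-128, 128-256, 256-512 with 2x downsampling after the first
  three blocks), frozen during training.  Its weights default to a
  fixed-seed random initialisation — a documented, accepted practice for
  perceptual losses — and external weights can be loaded from a
  checkpoint file.

All convolutions use shape-preserving padding (stride-2 layers halve
exactly), so generator outputs match input grids whose axes are divisible
by 8.  Weight initialisation is zero-mean Gaussian, sd 0.02, seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import CheckpointError, ConfigError, ShapeError

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "FeatureExtractorSpec",
    "ModelBundle",
    "UNetGenerator",
    "MultiContrastGenerator",
    "PatchDiscriminator",
    "FeatureExtractor",
    "build_generator",
    "build_discriminator",
    "build_feature_extractor",
    "save_bundle",
    "load_bundle",
]

TABLE1_ENCODER = (20, 40, 40, 80, 80, 160, 160, 320)
TABLE1_DECODER = (160, 160, 80, 80, 40, 40)
TABLE1_DISCRIMINATOR = (64, 128, 256, 512)
TABLE1_FEATURE_BLOCKS = ((32, 64), (64, 128), (128, 256), (256, 512))


def scaled_channels(channels, scale: int):
    """Divide a channel stack by an integer width factor (minimum 1)."""
    return tuple(max(1, c // scale) for c in channels)


@dataclass(frozen=True)
class GeneratorSpec:
    in_contrasts: int = 1
    out_decoders: int = 1
    encoder_channels: tuple = TABLE1_ENCODER
    decoder_channels: tuple = TABLE1_DECODER
    norm: bool = True
    pad_mode: str = "zeros"

    def __post_init__(self):
        if self.in_contrasts not in (1, 2) or self.out_decoders not in (1, 2):
            raise ConfigError("in_contrasts and out_decoders must be 1 or 2")
        if len(self.encoder_channels) != 8:
            raise ConfigError("encoder_channels must list 8 widths (4 stages x 2 convs)")
        if len(self.decoder_channels) != 6:
            raise ConfigError("decoder_channels must list 6 widths (3 stages x 2 convs)")


@dataclass(frozen=True)
class DiscriminatorSpec:
    channels: tuple = TABLE1_DISCRIMINATOR
    kernel: int = 4
    leaky_slope: float = 0.2
    norm: bool = True

    def __post_init__(self):
        if len(self.channels) != 4:
            raise ConfigError("discriminator needs 4 stride-2 channel widths")


@dataclass(frozen=True)
class FeatureExtractorSpec:
    block_channels: tuple = TABLE1_FEATURE_BLOCKS
    in_channels: int = 1
    norm: bool = True
    weights_source: str = "random-seeded"  # or a checkpoint path
    phi_after_pool: bool = True  # phi_m taken after the block's downsampling

    def __post_init__(self):
        if len(self.block_channels) != 4 or any(len(b) != 2 for b in self.block_channels):
            raise ConfigError("block_channels must be 4 (c1, c2) pairs")


def _conv_block(cin, cout, norm, rng, pad_mode="zeros"):
    layers = [nn.Conv3d(cin, cout, 3, 1, pad_mode=pad_mode, rng=rng)]
    if norm:
        layers.append(nn.InstanceNorm3d())
    layers.append(nn.ReLU())
    return nn.Sequential(*layers)


def _check_div8(shape):
    if any(s % 8 != 0 for s in shape):
        raise ShapeError(f"generator input axes must be divisible by 8, got {tuple(shape)}")


class _Encoder:
    """Four conv stages with 2x max pooling between them; exposes skips."""

    def __init__(self, cin, channels, norm, rng, pad_mode):
        e = channels
        self.stages = [
            nn.Sequential(_conv_block(cin, e[0], norm, rng, pad_mode),
                          _conv_block(e[0], e[1], norm, rng, pad_mode)),
            nn.Sequential(_conv_block(e[1], e[2], norm, rng, pad_mode),
                          _conv_block(e[2], e[3], norm, rng, pad_mode)),
            nn.Sequential(_conv_block(e[3], e[4], norm, rng, pad_mode),
                          _conv_block(e[4], e[5], norm, rng, pad_mode)),
            nn.Sequential(_conv_block(e[5], e[6], norm, rng, pad_mode),
                          _conv_block(e[6], e[7], norm, rng, pad_mode)),
        ]
        self.pools = [nn.MaxPool3d() for _ in range(3)]
        self.skip_channels = (e[1], e[3], e[5])
        self.out_channels = e[7]

    def params(self):
        out = []
        for s in self.stages:
            out.extend(s.params())
        return out

    def forward(self, x):
        skips = []
        h = x
        for i in range(3):
            h = self.stages[i].forward(h)
            skips.append(h)
            h = self.pools[i].forward(h)
        bottom = self.stages[3].forward(h)
        return bottom, skips

    def backward(self, g_bottom, g_skips):
        g = self.stages[3].backward(g_bottom)
        for i in (2, 1, 0):
            g = self.pools[i].backward(g)
            g = g + g_skips[i]
            g = self.stages[i].backward(g)
        return g


class _Decoder:
    """Three upsample+concat+conv stages and a 1x1x1 tanh head."""

    def __init__(self, in_channels, skip_channels, channels, norm, rng, pad_mode):
        d = channels
        sk = skip_channels
        self.ups = [nn.UpsampleNearest3d() for _ in range(3)]
        self.stages = [
            nn.Sequential(_conv_block(in_channels + sk[2], d[0], norm, rng, pad_mode),
                          _conv_block(d[0], d[1], norm, rng, pad_mode)),
            nn.Sequential(_conv_block(d[1] + sk[1], d[2], norm, rng, pad_mode),
                          _conv_block(d[2], d[3], norm, rng, pad_mode)),
            nn.Sequential(_conv_block(d[3] + sk[0], d[4], norm, rng, pad_mode),
                          _conv_block(d[4], d[5], norm, rng, pad_mode)),
        ]
        self.head = nn.Conv3d(d[5], 1, 1, 1, pad=0, rng=rng)
        self.tanh = nn.Tanh()
        self._split = None

    def params(self):
        out = []
        for s in self.stages:
            out.extend(s.params())
        out.extend(self.head.params())
        return out

    def forward(self, bottom, skips):
        h = bottom
        self._split = []
        for i, skip in enumerate(reversed(skips)):
            h = self.ups[i].forward(h)
            self._split.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
            h = self.stages[i].forward(h)
        return self.tanh.forward(self.head.forward(h))

    def backward(self, gy):
        g = self.head.backward(self.tanh.backward(gy))
        g_skips = [None, None, None]
        for i in (2, 1, 0):
            g = self.stages[i].backward(g)
            nc = self._split[i]
            g_up, g_skip = g[:nc], g[nc:]
            g_skips[2 - i] = g_skip  # stage 0 consumes the deepest skip
            g = self.ups[i].backward(g_up)
        return g, g_skips


class UNetGenerator:
    """Single-decoder 3D U-Net; callable on (C_in, D, H, W) grids."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        if spec.out_decoders != 1:
            raise ConfigError("UNetGenerator is single-decoder; use MultiContrastGenerator")
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
        self.encoder = _Encoder(spec.in_contrasts, spec.encoder_channels,
                                spec.norm, rng, spec.pad_mode)
        self.decoder = _Decoder(self.encoder.out_channels, self.encoder.skip_channels,
                                spec.decoder_channels, spec.norm, rng, spec.pad_mode)

    @property
    def n_outputs(self):
        return 1

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def forward(self, x):
        if x.shape[0] != self.spec.in_contrasts:
            raise ShapeError(
                f"expected {self.spec.in_contrasts} input channel(s), got {x.shape[0]}")
        _check_div8(x.shape[1:])
        bottom, skips = self.encoder.forward(x)
        return self.decoder.forward(bottom, skips)

    def backward(self, gy):
        g_bottom, g_skips = self.decoder.backward(gy)
        return self.encoder.backward(g_bottom, g_skips)

    def __call__(self, x):
        return self.forward(x)


class _GeneratorView:
    """Per-contrast handle onto a shared-encoder generator (G_T1 / G_T2)."""

    def __init__(self, parent, index):
        self.parent = parent
        self.index = index

    @property
    def encoder(self):
        return self.parent.encoder

    @property
    def decoder(self):
        return self.parent.decoders[self.index]

    def __call__(self, x):
        return self.parent.forward(x)[self.index]


class MultiContrastGenerator:
    """Shared encoder, two independent decoders (predicted T1w and T2w).

    Input is the channel-wise concatenation (T1 first, T2 second) of the
    two input-age contrasts; ``forward`` returns both predicted volumes.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        if spec.in_contrasts != 2 or spec.out_decoders != 2:
            raise ConfigError("MultiContrastGenerator requires in_contrasts=2, out_decoders=2")
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
        self.encoder = _Encoder(2, spec.encoder_channels, spec.norm, rng, spec.pad_mode)
        self.decoders = [
            _Decoder(self.encoder.out_channels, self.encoder.skip_channels,
                     spec.decoder_channels, spec.norm, rng, spec.pad_mode)
            for _ in range(2)
        ]
        self.views = (_GeneratorView(self, 0), _GeneratorView(self, 1))

    @property
    def n_outputs(self):
        return 2

    def params(self):
        out = self.encoder.params()
        for d in self.decoders:
            out.extend(d.params())
        return out

    def forward(self, x):
        if x.shape[0] != 2:
            raise ShapeError(f"expected 2 input channels (T1, T2), got {x.shape[0]}")
        _check_div8(x.shape[1:])
        bottom, skips = self.encoder.forward(x)
        return tuple(d.forward(bottom, skips) for d in self.decoders)

    def backward(self, gys):
        g_bottom = 0.0
        g_skips = [0.0, 0.0, 0.0]
        for d, gy in zip(self.decoders, gys):
            gb, gs = d.backward(gy)
            g_bottom = g_bottom + gb
            g_skips = [a + b for a, b in zip(g_skips, gs)]
        return self.encoder.backward(g_bottom, g_skips)

    def __call__(self, x):
        return self.forward(x)


class PatchDiscriminator:
    """Four stride-2 4^3 convolutions + stride-1 sigmoid head -> score map."""

    MIN_AXIS = 16

    def __init__(self, spec: DiscriminatorSpec, in_channels: int = 1, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
        k = spec.kernel
        layers = []
        cin = in_channels
        for i, cout in enumerate(spec.channels):
            layers.append(nn.Conv3d(cin, cout, k, 2, pad=1, rng=rng))
            if i > 0 and spec.norm:  # first layer carries no normalisation
                layers.append(nn.InstanceNorm3d())
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            cin = cout
        layers.append(nn.Conv3d(cin, 1, k, 1, pad=((1, 2),) * 3, rng=rng))
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, x):
        if x.ndim == 3:
            x = x[None]
        if min(x.shape[1:]) < self.MIN_AXIS:
            raise ShapeError(
                f"discriminator input axes must be >= {self.MIN_AXIS}, got {x.shape[1:]}")
        return self.net.forward(x)[0]

    def backward(self, gy):
        return self.net.backward(gy[None])

    def __call__(self, x):
        return self.forward(x)


class FeatureExtractor:
    """Frozen encoder with addressable per-block outputs phi_1..phi_4.

    ``features(x, m)`` returns the m-th block output; by default phi_1..3
    are taken *after* the block's 2x downsampling (so phi_1 of a 32^3
    single-channel input is 64 channels at 16^3) and phi_4 after the last
    block (512 channels, 4^3).  Parameters are excluded from every
    optimiser; ``backward_input`` propagates a feature-space gradient back
    to the input without touching parameter gradients.
    """

    def __init__(self, spec: FeatureExtractorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
        self.blocks = []
        self.pools = [nn.MaxPool3d() for _ in range(3)]
        cin = spec.in_channels
        for c1, c2 in spec.block_channels:
            self.blocks.append(nn.Sequential(_conv_block(cin, c1, spec.norm, rng),
                                             _conv_block(c1, c2, spec.norm, rng)))
            cin = c2
        if spec.weights_source not in ("random-seeded",):
            self.load_weights(spec.weights_source)
        self._trace = None

    def params(self):  # frozen: exposed for checkpointing only
        out = []
        for b in self.blocks:
            out.extend(b.params())
        return out

    def features(self, x, m: int):
        if not 1 <= m <= 4:
            raise ConfigError(f"feature layer m must be in 1..4, got {m}")
        if x.ndim == 3:
            x = x[None]
        _check_div8(x.shape[1:])
        self._trace = []
        h = x
        for i, block in enumerate(self.blocks):
            h = block.forward(h)
            self._trace.append(block)
            if i < 3:
                if self.spec.phi_after_pool:
                    h = self.pools[i].forward(h)
                    self._trace.append(self.pools[i])
                    if i + 1 == m:
                        return h
                else:
                    if i + 1 == m:
                        return h
                    h = self.pools[i].forward(h)
                    self._trace.append(self.pools[i])
        return h

    def backward_input(self, g):
        for layer in reversed(self._trace):
            g = layer.backward(g)
        return g[0] if g.shape[0] == 1 else g

    def save_weights(self, path) -> Path:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        arrays["fingerprint"] = np.array(json.dumps(asdict(self.spec), sort_keys=True))
        np.savez(path, **arrays)
        return path

    def load_weights(self, path):
        path = Path(path)
        if not path.exists():
            raise CheckpointError(f"feature-extractor weights not found: {path}")
        with np.load(path) as z:
            params = self.params()
            keys = [f"p{i}" for i in range(len(params))]
            if sorted(z.files) != sorted(keys + ["fingerprint"]):
                raise CheckpointError(f"{path} does not match the feature-extractor layout")
            for k, p in zip(keys, params):
                if z[k].shape != p.value.shape:
                    raise CheckpointError(
                        f"{path}: shape mismatch at {k}: {z[k].shape} vs {p.value.shape}")
            for k, p in zip(keys, params):
                p.value[...] = z[k]

    def __call__(self, x, m=4):
        return self.features(x, m)


def build_generator(spec: GeneratorSpec, seed: int = 0):
    """Construct the generator the spec describes (single or dual decoder)."""
    if spec.out_decoders == 2:
        return MultiContrastGenerator(spec, seed)
    return UNetGenerator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, in_channels: int = 1, seed: int = 0):
    return PatchDiscriminator(spec, in_channels, seed)


def build_feature_extractor(spec: FeatureExtractorSpec, seed: int = 0):
    return FeatureExtractor(spec, seed)


@dataclass
class ModelBundle:
    """Generator(s), discriminator(s) and the frozen feature extractor.

    For the multi-contrast configuration ``generator`` is a
    :class:`MultiContrastGenerator` whose two per-contrast views share one
    encoder object; ``discriminators`` holds one patch discriminator per
    output contrast.
    """

    generator: object
    discriminators: list
    feature_extractor: FeatureExtractor
    generator_spec: GeneratorSpec
    discriminator_spec: DiscriminatorSpec
    feature_spec: FeatureExtractorSpec
    direction: str = "6to12"
    contrasts_out: tuple = ("T1w",)

    def generator_params(self):
        return self.generator.params()

    def discriminator_params(self):
        out = []
        for d in self.discriminators:
            out.extend(d.params())
        return out

    def parameter_counts(self) -> dict:
        return {
            "generator": nn.parameter_count(self.generator.params()),
            "discriminators": nn.parameter_count(self.discriminator_params()),
            "feature_extractor": nn.parameter_count(self.feature_extractor.params()),
        }

    def fingerprint(self) -> str:
        return json.dumps(
            {
                "generator": asdict(self.generator_spec),
                "discriminator": asdict(self.discriminator_spec),
                "feature": asdict(self.feature_spec),
                "direction": self.direction,
                "contrasts_out": list(self.contrasts_out),
            },
            sort_keys=True,
        )


def make_bundle(gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
                feat_spec: FeatureExtractorSpec, seed: int = 0,
                direction: str = "6to12", contrasts_out=("T1w",)) -> ModelBundle:
    ss = np.random.SeedSequence([int(seed), 23]).generate_state(4)
    gen = build_generator(gen_spec, int(ss[0]))
    discs = [build_discriminator(disc_spec, 1, int(ss[1]) + i)
             for i in range(gen_spec.out_decoders)]
    feat = build_feature_extractor(feat_spec, int(ss[2]))
    return ModelBundle(gen, discs, feat, gen_spec, disc_spec, feat_spec,
                       direction, tuple(contrasts_out))


def save_bundle(bundle: ModelBundle, path) -> Path:
    """Single-file .npz checkpoint with an embedded spec fingerprint."""
    path = Path(path)
    arrays = {"fingerprint": np.array(bundle.fingerprint())}
    for group, params in (("g", bundle.generator_params()),
                          ("d", bundle.discriminator_params()),
                          ("f", bundle.feature_extractor.params())):
        for i, p in enumerate(params):
            arrays[f"{group}{i}"] = p.value
    np.savez(path, **arrays)
    return path


def load_bundle(path, template: ModelBundle) -> ModelBundle:
    """Load weights into a freshly built bundle of the same specs.

    Refuses to load when the stored fingerprint differs from the
    template's.
    """
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        if "fingerprint" not in z.files:
            raise CheckpointError(f"{path} is not a model checkpoint")
        stored = str(z["fingerprint"])
        if stored != template.fingerprint():
            raise CheckpointError(
                f"{path}: checkpoint fingerprint does not match the requested architecture")
        for group, params in (("g", template.generator_params()),
                              ("d", template.discriminator_params()),
                              ("f", template.feature_extractor.params())):
            for i, p in enumerate(params):
                key = f"{group}{i}"
                if key not in z.files or z[key].shape != p.value.shape:
                    raise CheckpointError(f"{path}: missing or mismatched array {key}")
                p.value[...] = z[key]
    return template
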