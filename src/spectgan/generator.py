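"""Conditional light-weight generator.

The generator follows the few-shot FastGAN design scaled to a 64x64
matrix: a fully connected layer embeds the concatenated (latent,
condition) input into a 64-dimensional vector, an input block lifts it to
a 4x4 feature map, four up-sampling blocks (nearest-neighbour upsampling,
3x3 convolution, GLU) grow it to 64x64, and an output block emits a
single-channel image through tanh.  A single skip-layer excitation module
gates the 32x32 feature map with a self-gating signal computed from the
8x8 map, giving a short gradient path between distant layers.

Latent vectors are 256-dimensional standard-normal draws; the condition
is the one-hot vector of :mod:`spectgan.conditioning`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditioning import ConditionVector, Variant, encode_condition
from .nn import BatchNorm2d, Conv2d, Linear, Module, Tensor, concat, glu, upsample_nearest
from .slices import MATRIX_SIZE, Level, Pattern

__all__ = [
    "GeneratorConfig",
    "Generator",
    "SkipLayerExcitation",
    "NetworkError",
    "build_generator",
    "generate",
    "sample_latent",
    "to_unit_range",
]

LATENT_DIM = 256
EMBED_DIM = 64


class NetworkError(ValueError):
    """Raised on shape/variant mismatches in the networks."""


@dataclass(frozen=True)
class GeneratorConfig:
    variant: Variant = Variant.A
    latent_dim: int = LATENT_DIM
    embed_dim: int = EMBED_DIM
    base_channels: int = 256  # width of the 4x4 feature map; halves per scale
    seed: int = 0

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        """Widths at 4, 8, 16, 32 and 64 px."""
        c = self.base_channels
        return (c, max(c // 2, 4), max(c // 4, 4), max(c // 8, 4), max(c // 8, 4))


class SkipLayerExcitation(Module):
    """Channelwise self-gating of a high-resolution map by a low-resolution one.

    The low-resolution map is reduced to 1x1 by two unpadded convolutions
    with a leaky-ReLU between them; a sigmoid turns the result into
    per-channel gates in (0, 1) which multiply the high-resolution map.
    """

    def __init__(
        self, low_channels: int, high_channels: int, low_size: int,
        rng: np.random.Generator,
    ):
        mid = (low_size - 4) // 2 + 1
        if mid < 1:
            raise NetworkError(f"low-res map of size {low_size} too small for SLE")
        self.low_size = low_size
        self.high_channels = high_channels
        self.conv1 = Conv2d(low_channels, high_channels, 4, rng, stride=2, padding=0)
        self.conv2 = Conv2d(high_channels, high_channels, mid, rng, padding=0)

    def __call__(self, low_res: Tensor, high_res: Tensor) -> Tensor:
        if low_res.shape[2] >= high_res.shape[2]:
            raise NetworkError("low_res map must be spatially smaller than high_res")
        if high_res.shape[1] != self.high_channels:
            raise NetworkError(
                f"gate channels {self.high_channels} do not match "
                f"high_res channels {high_res.shape[1]}"
            )
        gate = self.conv2(self.conv1(low_res).leaky_relu(0.1)).sigmoid()
        return high_res * gate


class _UpBlock(Module):
    """Nearest-neighbour x2 upsampling, 3x3 same-padded conv, batch norm, GLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, 2 * out_ch, 3, rng, padding=1)
        self.bn = BatchNorm2d(2 * out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return glu(self.bn(self.conv(upsample_nearest(x, 2))))


class Generator(Module):
    def __init__(self, config: GeneratorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c4, c8, c16, c32, c64 = config.channel_schedule
        cond_dim = config.variant.n_bits
        self.embed = Linear(config.latent_dim + cond_dim, config.embed_dim, rng)
        # input block: a learned lift of the embedding to a 4x4 map (the
        # 1x1 -> 4x4 transposed convolution of the reference design is
        # exactly a linear map to 4x4 positions), followed by GLU
        self.input_lift = Linear(config.embed_dim, 2 * c4 * 16, rng)
        self.input_bn = BatchNorm2d(2 * c4)
        self.up8 = _UpBlock(c4, c8, rng)
        self.up16 = _UpBlock(c8, c16, rng)
        self.up32 = _UpBlock(c16, c32, rng)
        self.sle = SkipLayerExcitation(c8, c32, low_size=8, rng=rng)
        self.up64 = _UpBlock(c32, c64, rng)
        self.output_conv = Conv2d(c64, 1, 3, rng, padding=1)

    @property
    def variant(self) -> Variant:
        return self.config.variant

    def __call__(self, z: Tensor, y: np.ndarray) -> Tensor:
        """Synthesize a batch: z (N, latent_dim), y (N, cond_dim) -> (N, 1, 64, 64)."""
        n, d = z.shape
        if d != self.config.latent_dim:
            raise NetworkError(
                f"latent dimension {d} != configured {self.config.latent_dim}"
            )
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (n, self.config.variant.n_bits):
            raise NetworkError(
                f"condition batch shape {y.shape} incompatible with variant "
                f"{self.config.variant.value}"
            )
        h = self.embed(concat([z, Tensor(y)], axis=1))
        c4 = self.config.channel_schedule[0]
        x4 = glu(self.input_bn(self.input_lift(h).reshape(n, 2 * c4, 4, 4)))
        x8 = self.up8(x4)
        x16 = self.up16(x8)
        x32 = self.sle(x8, self.up32(x16))
        x64 = self.up64(x32)
        return self.output_conv(x64).tanh()


def build_generator(config: GeneratorConfig) -> Generator:
    """Construct a generator with seeded normal(0, 0.02) initialization."""
    return Generator(config)


def sample_latent(n: int, rng: np.random.Generator, dim: int = LATENT_DIM) -> Tensor:
    """Draw ``n`` standard-normal latent vectors."""
    return Tensor(rng.normal(size=(n, dim)))


def to_unit_range(images: np.ndarray) -> np.ndarray:
    """Map tanh-range images from [-1, 1] to the normalized-count range [0, 1]."""
    return np.clip((np.asarray(images) + 1.0) / 2.0, 0.0, 1.0)


def generate(
    params: Generator, z: Tensor | np.ndarray, y: ConditionVector
) -> np.ndarray:
    """Synthesize a single 64x64 image (tanh range) from one latent draw."""
    if y.variant != params.variant:
        raise NetworkError(
            f"condition variant {y.variant.value} does not match generator "
            f"variant {params.variant.value}"
        )
    z = z if isinstance(z, Tensor) else Tensor(z)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    out = params(z, y.as_array()[None, :])
    return out.data[0, 0]


def sample_images(
    params: Generator,
    level: Level,
    pattern: Pattern,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``n`` images for one class, returned in [0, 1], shape (n, 64, 64)."""
    y = encode_condition(level, pattern, params.variant)
    z = sample_latent(n, rng, params.config.latent_dim)
    out = params(z, np.tile(y.as_array(), (n, 1)))
    return to_unit_range(out.data[:, 0])
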