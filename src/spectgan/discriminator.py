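"""Conditional discriminator with self-supervised reconstruction decoders.

The discriminator consumes the (real or generated) image concatenated
channelwise with the condition image, passes it through an input block
and three strided down-sampling blocks, and scores authenticity with an
unbounded real/fake logit.  The feature maps of the second (8x8, B1) and
third (4x4, B2) down-sampling blocks feed two simple decoders used only
on real images: the regional decoder reconstructs a random half-size crop
of the input from a matching crop of B1, the global decoder reconstructs
the whole input from B2.  All convolutions on the critic path are
spectrally normalized; activations are leaky ReLU with slope 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditioning import Variant
from .generator import NetworkError
from .nn import BatchNorm2d, Conv2d, Module, Tensor, glu, upsample_nearest

__all__ = [
    "DiscriminatorConfig",
    "Discriminator",
    "build_discriminator",
    "crop_regional",
    "crop_image_like",
]


@dataclass(frozen=True)
class DiscriminatorConfig:
    variant: Variant = Variant.A
    base_channels: int = 32  # width after the input block (32x32 map)
    seed: int = 0


class _Decoder(Module):
    """Two upsample+conv stages reconstructing an image from a 4x4 map."""

    def __init__(
        self, in_ch: int, mid_ch: int, factors: tuple[int, int],
        rng: np.random.Generator,
    ):
        self.f1, self.f2 = factors
        self.conv1 = Conv2d(in_ch, 2 * mid_ch, 3, rng, padding=1)
        self.bn = BatchNorm2d(2 * mid_ch)
        self.conv2 = Conv2d(mid_ch, 1, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = glu(self.bn(self.conv1(upsample_nearest(x, self.f1))))
        return self.conv2(upsample_nearest(h, self.f2)).sigmoid()


class Discriminator(Module):
    def __init__(self, config: DiscriminatorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        in_ch = 1 + config.variant.n_bits
        sn = dict(spectral_norm=True)
        self.input_conv = Conv2d(in_ch, b, 4, rng, stride=2, padding=1, **sn)
        self.down1 = Conv2d(b, 2 * b, 4, rng, stride=2, padding=1, **sn)
        self.down2 = Conv2d(2 * b, 4 * b, 4, rng, stride=2, padding=1, **sn)
        self.down3 = Conv2d(4 * b, 8 * b, 4, rng, stride=2, padding=1, **sn)
        self.out_conv1 = Conv2d(8 * b, 8 * b, 3, rng, padding=1, **sn)
        self.out_conv2 = Conv2d(8 * b, 1, 4, rng, padding=0, **sn)
        self.decoder_regional = _Decoder(4 * b, b, (4, 2), rng)
        self.decoder_global = _Decoder(8 * b, b, (4, 4), rng)

    @property
    def variant(self) -> Variant:
        return self.config.variant

    def __call__(
        self, image: Tensor, cond_image: np.ndarray
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Score a batch.

        ``image``: (N, 1, 64, 64) in tanh range; ``cond_image``: (N, C, 64, 64)
        constant one-hot channels.  Returns (logits (N,), B1 (N,4b,8,8),
        B2 (N,8b,4,4)).
        """
        n = image.shape[0]
        cond_image = np.asarray(cond_image, dtype=np.float64)
        if cond_image.shape[1] != self.config.variant.n_bits:
            raise NetworkError(
                f"condition image has {cond_image.shape[1]} channels; variant "
                f"{self.config.variant.value} expects {self.config.variant.n_bits}"
            )
        from .nn import concat

        x = concat([image, Tensor(cond_image)], axis=1)
        h = self.input_conv(x).leaky_relu(0.1)
        h = self.down1(h).leaky_relu(0.1)
        b1 = self.down2(h).leaky_relu(0.1)
        b2 = self.down3(b1).leaky_relu(0.1)
        out = self.out_conv1(b2).leaky_relu(0.1)
        logits = self.out_conv2(out).reshape(n)
        return logits, b1, b2


def build_discriminator(config: DiscriminatorConfig) -> Discriminator:
    return Discriminator(config)


def crop_regional(
    feature: Tensor, rng: np.random.Generator
) -> tuple[Tensor, tuple[int, int]]:
    """Crop a random half-height, half-width window from an NCHW feature map.

    Returns the crop and its (row, col) offset so the matching image-space
    crop can be taken at the scaled location.
    """
    _, _, h, w = feature.shape
    if h % 2 or w % 2:
        raise NetworkError("regional crop requires even feature dimensions")
    r0 = int(rng.integers(0, h // 2 + 1))
    c0 = int(rng.integers(0, w // 2 + 1))
    return feature[:, :, r0 : r0 + h // 2, c0 : c0 + w // 2], (r0, c0)


def crop_image_like(
    images: np.ndarray, location: tuple[int, int], feature_size: int
) -> np.ndarray:
    """Image-space crop matching a feature-space crop.

    For a feature map at 1/k of the image resolution, the image offset is
    k times the feature offset and the window is half the image size.
    """
    r0, c0 = location
    h = images.shape[-2]
    k = h // feature_size
    half = h // 2
    return images[..., k * r0 : k * r0 + half, k * c0 : k * c0 + half]
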