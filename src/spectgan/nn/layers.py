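"""Neural-network layers built on the autodiff engine.

Weight initialization is normal(0, 0.02) throughout, the convention of
light-weight GAN implementations.  Convolutions in the discriminator use
spectral normalization (power iteration on the flattened kernel), which
stabilizes hinge-loss adversarial training.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autodiff import Tensor, conv2d

INIT_STD = 0.02


class Module:
    """Minimal module base: parameter discovery + state (de)serialization."""

    def parameters(self) -> Iterator[Tensor]:
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3x3/4x4 convolution, optionally spectrally normalized.

    With ``spectral_norm=True`` the effective kernel is W / sigma(W), where
    sigma is the largest singular value of W flattened to (out, in*kh*kw),
    estimated by one power-iteration step per forward pass.  The gradient
    flows through the normalization with the singular vectors held fixed.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        spectral_norm: bool = False,
    ):
        self.weight = Tensor(
            rng.normal(
                0.0, INIT_STD, size=(out_channels, in_channels, kernel_size, kernel_size)
            ),
            requires_grad=True,
        )
        self.bias: Optional[Tensor] = (
            Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        )
        self.stride = stride
        self.padding = padding
        self.spectral_norm = spectral_norm
        if spectral_norm:
            n = self.weight.data.reshape(out_channels, -1).shape[1]
            self._u = rng.normal(size=out_channels)
            self._u /= np.linalg.norm(self._u)
            self._v = np.zeros(n)
            self._w_version = None

    def _normalized_weight(self) -> Tensor:
        w_mat = self.weight.reshape(self.weight.shape[0], -1)
        wd = w_mat.data
        # one power-iteration step per weight update; repeated forwards on
        # unchanged weights reuse the cached vectors so inference is
        # deterministic
        if self._w_version != id(self.weight.data):
            v = wd.T @ self._u
            v /= np.linalg.norm(v) + 1e-12
            u = wd @ v
            u /= np.linalg.norm(u) + 1e-12
            self._u, self._v = u, v
            self._w_version = id(self.weight.data)
        sigma = (
            Tensor(self._u.reshape(1, -1)) @ w_mat @ Tensor(self._v.reshape(-1, 1))
        )
        return self.weight / sigma.reshape(1, 1, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        w = self._normalized_weight() if self.spectral_norm else self.weight
        return conv2d(x, w, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W) with learnable affine.

    Batch statistics are used at sampling time as well (generative batches
    are self-contained), the common choice for small-batch GAN generators.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


def glu(x: Tensor) -> Tensor:
    """Gated linear unit over the channel axis: a * sigmoid(b)."""
    c = x.shape[1]
    if c % 2:
        raise ValueError("GLU requires an even channel count")
    a = x[:, : c // 2]
    b = x[:, c // 2 :]
    return a * b.sigmoid()
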