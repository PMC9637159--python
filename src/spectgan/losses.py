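"""Adversarial and reconstruction losses.

The adversarial objective is the hinge loss: the discriminator pushes
real logits above +1 and fake logits below -1, while the generator
maximizes the discriminator's score on its samples,

    L_G    = -E[ D(G(z|y)) ]
    L_real = -E[ min(0, -1 + D(x)) ]
    L_fake = -E[ min(0, -1 - D(x_hat)) ]
    L_D    = L_real + L_fake + L_recon

L_recon is the self-supervised reconstruction term, evaluated on real
images only: the mean absolute error between the regional decoder output
and the matching crop of the input, plus that between the global decoder
output and the whole input (targets in the normalized [0, 1] range).
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

__all__ = [
    "LossError",
    "loss_generator",
    "loss_real",
    "loss_fake",
    "loss_recon",
    "loss_discriminator_total",
]


class LossError(ValueError):
    """Raised for empty logit batches or mismatched reconstruction shapes."""


def _as_array(logits) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(logits, dtype=np.float64))
    if arr.size == 0:
        raise LossError("empty logit batch")
    return arr


def loss_generator(fake_logits):
    """Hinge generator loss: negative mean of the fake logits."""
    if isinstance(fake_logits, Tensor):
        if fake_logits.data.size == 0:
            raise LossError("empty logit batch")
        return -fake_logits.mean()
    return float(-_as_array(fake_logits).mean())


def loss_real(real_logits):
    """Hinge loss on real logits: -E[min(0, -1 + D(x))]; zero iff all >= 1."""
    if isinstance(real_logits, Tensor):
        if real_logits.data.size == 0:
            raise LossError("empty logit batch")
        return -((real_logits - 1.0).minimum(0.0).mean())
    return float(-np.minimum(0.0, -1.0 + _as_array(real_logits)).mean())


def loss_fake(fake_logits):
    """Hinge loss on fake logits: -E[min(0, -1 - D(x_hat))]; zero iff all <= -1."""
    if isinstance(fake_logits, Tensor):
        if fake_logits.data.size == 0:
            raise LossError("empty logit batch")
        return -((-fake_logits - 1.0).minimum(0.0).mean())
    return float(-np.minimum(0.0, -1.0 - _as_array(fake_logits)).mean())


def loss_recon(regional_recon, regional_target, global_recon, global_target):
    """Self-supervised reconstruction loss (mean absolute error, real images).

    Each term is the MAE between a decoder output and its target, averaged
    over pixels and the batch; the two terms are summed.
    """
    reg_t = np.asarray(regional_target, dtype=np.float64)
    glo_t = np.asarray(global_target, dtype=np.float64)
    keep = isinstance(regional_recon, Tensor) or isinstance(global_recon, Tensor)
    reg = regional_recon if isinstance(regional_recon, Tensor) else None
    glo = global_recon if isinstance(global_recon, Tensor) else None
    reg_shape = reg.shape if reg is not None else np.asarray(regional_recon).shape
    glo_shape = glo.shape if glo is not None else np.asarray(global_recon).shape
    if reg_shape != reg_t.shape:
        raise LossError(f"regional shapes differ: {reg_shape} vs {reg_t.shape}")
    if glo_shape != glo_t.shape:
        raise LossError(f"global shapes differ: {glo_shape} vs {glo_t.shape}")
    if keep:
        reg = reg if reg is not None else Tensor(np.asarray(regional_recon))
        glo = glo if glo is not None else Tensor(np.asarray(global_recon))
        return (reg - Tensor(reg_t)).abs().mean() + (glo - Tensor(glo_t)).abs().mean()
    return float(
        np.abs(np.asarray(regional_recon, dtype=np.float64) - reg_t).mean()
        + np.abs(np.asarray(global_recon, dtype=np.float64) - glo_t).mean()
    )


def loss_discriminator_total(l_real, l_fake, l_recon):
    """Total discriminator loss: L_real + L_fake + L_recon."""
    return l_real + l_fake + l_recon
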