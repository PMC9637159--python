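"""Data augmentation for real training slices.

Three augmentations enlarge the effective training set:

* weighted averaging of a slice with its adjacent craniocaudal neighbor,
  z = w*z1 + (1-w)*z2 with w uniform on [0, 1];
* translation by t pixels (t a random integer in [-2, 2]) along the
  anteroposterior axis (array rows), zero-filling vacated pixels;
* horizontal (left-right) flips, applied only to normal and bilateral
  patterns — flipping a unilateral slice would silently swap the defect
  side and corrupt its label.
"""

from __future__ import annotations

import numpy as np

from .slices import Pattern, SpectSlice

__all__ = [
    "AugmentError",
    "augment_weighted_average",
    "augment_translate",
    "augment_hflip",
]

MAX_TRANSLATION = 2


class AugmentError(ValueError):
    """Raised for invalid augmentation arguments."""


def augment_weighted_average(z1: SpectSlice, z2: SpectSlice, w: float) -> SpectSlice:
    """Pixelwise convex combination w*z1 + (1-w)*z2; labels come from z1."""
    if not 0.0 <= w <= 1.0:
        raise AugmentError("weight w must lie in [0, 1]")
    if z1.pixels.shape != z2.pixels.shape:
        raise AugmentError("slices must share a shape")
    return z1.with_pixels(w * z1.pixels + (1.0 - w) * z2.pixels)


def augment_translate(s: SpectSlice, t: int) -> SpectSlice:
    """Shift slice content by ``t`` pixels anteroposteriorly (rows), |t| <= 2."""
    t = int(t)
    if abs(t) > MAX_TRANSLATION:
        raise AugmentError(f"|t| must be <= {MAX_TRANSLATION}, got {t}")
    if t == 0:
        return s.with_pixels(s.pixels.copy())
    out = np.zeros_like(s.pixels)
    if t > 0:
        out[t:, :] = s.pixels[:-t, :]
    else:
        out[:t, :] = s.pixels[-t:, :]
    return s.with_pixels(out)


def augment_hflip(s: SpectSlice) -> SpectSlice:
    """Mirror a slice across the midline; forbidden for unilateral slices."""
    if s.pattern == Pattern.UNILATERAL:
        raise AugmentError("horizontal flip would swap the defect side")
    return s.with_pixels(s.pixels[:, ::-1].copy())
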