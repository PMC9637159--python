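"""One-hot condition encodings for the conditional GAN.

Two dataset variants are supported.  Variant 'A' conditions on both the
anatomical level and the perfusion pattern: a 6-bit vector whose first
three positions one-hot the level (CER, BG, COR) and last three the
pattern (normal, unilateral, bilateral).  Variant 'B' uses cortical slices
only and conditions on the pattern alone (3 bits).

The generator receives the condition as a vector concatenated with the
latent; the discriminator receives it as spatially-constant image
channels (one channel per bit).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .slices import Level, Pattern

__all__ = [
    "Variant",
    "ConditionVector",
    "ConditionError",
    "encode_condition",
    "decode_condition",
    "condition_image",
]

_LEVEL_ORDER = (Level.CER, Level.BG, Level.COR)
_PATTERN_ORDER = (Pattern.NORMAL, Pattern.UNILATERAL, Pattern.BILATERAL)


class Variant(str, Enum):
    A = "A"
    B = "B"

    @property
    def n_bits(self) -> int:
        return 6 if self is Variant.A else 3


class ConditionError(ValueError):
    """Raised for invalid (level, pattern, variant) combinations or codes."""


@dataclass(frozen=True)
class ConditionVector:
    bits: tuple[int, ...]
    variant: Variant

    def __post_init__(self):
        if len(self.bits) != self.variant.n_bits:
            raise ConditionError(
                f"variant {self.variant.value} expects {self.variant.n_bits} bits, "
                f"got {len(self.bits)}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise ConditionError("condition bits must be 0 or 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.float64)


def encode_condition(level: Level, pattern: Pattern, variant: Variant) -> ConditionVector:
    """Encode (level, pattern) as the variant's one-hot condition vector."""
    level, pattern, variant = Level(level), Pattern(pattern), Variant(variant)
    pattern_bits = tuple(int(pattern == p) for p in _PATTERN_ORDER)
    if variant is Variant.B:
        if level != Level.COR:
            raise ConditionError("variant B encodes cortical slices only")
        return ConditionVector(pattern_bits, variant)
    level_bits = tuple(int(level == l) for l in _LEVEL_ORDER)
    return ConditionVector(level_bits + pattern_bits, variant)


def decode_condition(vector: ConditionVector) -> tuple[Level, Pattern]:
    """Inverse of :func:`encode_condition` (for manifests and reports)."""
    bits = vector.bits
    if vector.variant is Variant.B:
        if sum(bits) != 1:
            raise ConditionError(f"malformed variant-B code {bits}")
        return Level.COR, _PATTERN_ORDER[bits.index(1)]
    level_bits, pattern_bits = bits[:3], bits[3:]
    if sum(level_bits) != 1 or sum(pattern_bits) != 1:
        raise ConditionError(f"malformed variant-A code {bits}")
    return _LEVEL_ORDER[level_bits.index(1)], _PATTERN_ORDER[pattern_bits.index(1)]


def condition_image(vector: ConditionVector, height: int, width: int) -> np.ndarray:
    """Broadcast a condition vector to (C, height, width) constant channels."""
    if height <= 0 or width <= 0:
        raise ConditionError("condition image dimensions must be positive")
    return np.broadcast_to(
        vector.as_array()[:, None, None], (len(vector.bits), height, width)
    ).copy()
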