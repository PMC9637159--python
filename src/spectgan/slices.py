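"""Core domain types: labelled 64x64 perfusion-SPECT slices.

A slice is an axial cerebral-blood-flow image at one of three anatomical
levels — cerebellum (CER), basal ganglia (BG) or cortex (COR) — carrying a
perfusion pattern label: normal, unilateral defect (one hypoperfused
hemisphere) or bilateral defect.  Array convention: axis 0 is the
anteroposterior direction (rows), axis 1 is left-right (columns); by
default the left hemisphere is the left half of the stored array
(columns 0-31).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

MATRIX_SIZE = 64


class Level(str, Enum):
    CER = "cer"
    BG = "bg"
    COR = "cor"


class Pattern(str, Enum):
    NORMAL = "normal"
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class SliceError(ValueError):
    """Raised for invalid slice label combinations or degenerate pixel data."""


@dataclass
class SpectSlice:
    """A 64x64 nonnegative intensity array with level/pattern labels.

    ``neighbor`` optionally holds the adjacent craniocaudal slice used by
    the weighted-average augmentation.
    """

    pixels: np.ndarray
    level: Level
    pattern: Pattern
    side: Side = Side.NONE
    neighbor: Optional["SpectSlice"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (MATRIX_SIZE, MATRIX_SIZE):
            raise SliceError(
                f"slice matrix must be {MATRIX_SIZE}x{MATRIX_SIZE}, "
                f"got {self.pixels.shape}"
            )
        if np.any(self.pixels < 0):
            raise SliceError("slice pixels must be nonnegative")
        if (self.side == Side.NONE) != (self.pattern != Pattern.UNILATERAL):
            raise SliceError(
                f"side={self.side.value} inconsistent with pattern={self.pattern.value}"
            )

    def with_pixels(self, pixels: np.ndarray) -> "SpectSlice":
        """Copy of this slice with new pixel data (labels preserved)."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


def normalize_slice(s: SpectSlice) -> SpectSlice:
    """Divide a slice by its maximum count, so the output maximum is 1."""
    peak = float(s.pixels.max())
    if peak <= 0:
        raise SliceError("cannot normalize an all-zero slice")
    return s.with_pixels(s.pixels / peak)
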