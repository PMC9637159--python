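"""Synthetic brain-perfusion phantom slices.

The clinical tracer-uptake scans the model is designed for cannot be
shipped, so this module builds 64x64 phantoms with the same statistical
structure: three anatomical levels with distinct internal geometry
(cerebellum: two paramedian lobes; basal-ganglia level: cortical rim plus
central high-uptake nuclei; cortical level: cortical rim with a
lower-uptake interior), three perfusion patterns (normal, unilateral and
bilateral hypoperfusion) and Poisson counting noise.  A hypoperfusion
defect of ``contrast`` c multiplies the affected hemisphere's expected
counts by (1 - c).

Every slice can carry a correlated "adjacent craniocaudal" neighbor,
produced by a smooth random deformation of the parent plus independent
counting noise, which the training augmentation interpolates against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .slices import MATRIX_SIZE, Level, Pattern, Side, SliceError, SpectSlice

__all__ = [
    "PhantomGeometry",
    "DatasetComposition",
    "TABLE1_COUNTS",
    "make_phantom_slice",
    "make_neighbor",
    "build_dataset",
]

# Slice counts per (level, pattern) cell of the reference training set:
# rows cerebellum / basal ganglia / cortex, columns normal / uni / bilateral.
TABLE1_COUNTS: dict[tuple[Level, Pattern], int] = {
    (Level.CER, Pattern.NORMAL): 248,
    (Level.CER, Pattern.UNILATERAL): 66,
    (Level.CER, Pattern.BILATERAL): 0,
    (Level.BG, Pattern.NORMAL): 174,
    (Level.BG, Pattern.UNILATERAL): 116,
    (Level.BG, Pattern.BILATERAL): 44,
    (Level.COR, Pattern.NORMAL): 129,
    (Level.COR, Pattern.UNILATERAL): 109,
    (Level.COR, Pattern.BILATERAL): 52,
}


@dataclass(frozen=True)
class PhantomGeometry:
    """Tunable phantom geometry (pixel units on the 64x64 grid)."""

    center: tuple[float, float] = (32.0, 31.5)
    # (anteroposterior, left-right) ellipse semi-axes per level
    semi_axes: dict = field(
        default_factory=lambda: {
            Level.CER: (22.0, 24.0),
            Level.BG: (26.0, 22.0),
            Level.COR: (25.0, 21.0),
        }
    )
    rim_inner: float = 0.70  # cortical rim spans rim_inner..1.0 of the radius
    background: dict = field(
        default_factory=lambda: {Level.CER: 0.45, Level.BG: 0.40, Level.COR: 0.35}
    )
    rim_intensity: dict = field(
        default_factory=lambda: {Level.BG: 0.75, Level.COR: 0.85}
    )
    lobe_offset: float = 9.0  # cerebellar lobe distance from midline
    lobe_row: float = 40.0
    lobe_sigma: float = 6.5
    lobe_amplitude: float = 0.60
    nucleus_offset: float = 7.0  # basal-ganglia nucleus distance from midline
    nucleus_sigma: float = 4.0
    nucleus_amplitude: float = 0.55
    smooth_sigma: float = 1.5
    # post-reconstruction filter applied after the Poisson draw; clinical
    # SPECT reconstructions are low-pass filtered, so counting noise in the
    # final slice is spatially correlated rather than pixelwise independent
    post_smooth_sigma: float = 1.2
    count_scale_range: tuple[float, float] = (80.0, 160.0)


DEFAULT_GEOMETRY = PhantomGeometry()


@dataclass(frozen=True)
class DatasetComposition:
    """Mapping (level, pattern) -> slice count."""

    counts: dict

    def __post_init__(self):
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {key}")

    @classmethod
    def table1(cls) -> "DatasetComposition":
        return cls(dict(TABLE1_COUNTS))

    @classmethod
    def scaled(cls, total: int) -> "DatasetComposition":
        """Reference composition rescaled to ``total`` slices.

        Cell counts keep their proportions (largest-remainder rounding), so
        empty cells stay empty and the class imbalance is preserved.
        """
        grand = sum(TABLE1_COUNTS.values())
        raw = {k: v * total / grand for k, v in TABLE1_COUNTS.items()}
        counts = {k: int(np.floor(x)) for k, x in raw.items()}
        short = total - sum(counts.values())
        for k in sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)[
            :short
        ]:
            counts[k] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _expected_field(
    level: Level, geometry: PhantomGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Noise-free expected-count field for one anatomical level.

    Structure positions are jittered slightly per slice so a population of
    phantoms exhibits inter-slice anatomical variability.
    """
    r0, c0 = geometry.center
    ar, ac = geometry.semi_axes[level]
    jr, jc = rng.normal(0.0, 0.6, size=2)
    rows, cols = np.mgrid[0:MATRIX_SIZE, 0:MATRIX_SIZE]
    radius = np.sqrt(
        ((rows - r0 - jr) / ar) ** 2 + ((cols - c0 - jc) / ac) ** 2
    )
    tissue = radius <= 1.0

    fld = np.zeros((MATRIX_SIZE, MATRIX_SIZE))
    fld[tissue] = geometry.background[level]

    def blob(row, col, sigma, amp):
        return amp * np.exp(
            -(((rows - row) ** 2 + (cols - col) ** 2) / (2.0 * sigma**2))
        )

    if level == Level.CER:
        row = geometry.lobe_row + jr + rng.normal(0.0, 0.5)
        off = geometry.lobe_offset + rng.normal(0.0, 0.4)
        for sign in (-1.0, 1.0):
            fld += tissue * blob(
                row, c0 + jc + sign * off, geometry.lobe_sigma, geometry.lobe_amplitude
            )
    else:
        rim = tissue & (radius >= geometry.rim_inner)
        fld[rim] = geometry.rim_intensity[level]
        if level == Level.BG:
            off = geometry.nucleus_offset + rng.normal(0.0, 0.4)
            row = r0 + jr + rng.normal(0.0, 0.5)
            for sign in (-1.0, 1.0):
                fld += tissue * blob(
                    row,
                    c0 + jc + sign * off,
                    geometry.nucleus_sigma,
                    geometry.nucleus_amplitude,
                )
    return ndimage.gaussian_filter(fld, geometry.smooth_sigma)


def _apply_defect(
    fld: np.ndarray, pattern: Pattern, side: Side, contrast: float
) -> np.ndarray:
    """Multiply hypoperfused hemisphere(s) by (1 - contrast)."""
    out = fld.copy()
    half = MATRIX_SIZE // 2
    if pattern == Pattern.UNILATERAL:
        sl = slice(0, half) if side == Side.LEFT else slice(half, MATRIX_SIZE)
        out[:, sl] *= 1.0 - contrast
    elif pattern == Pattern.BILATERAL:
        out *= 1.0 - contrast
    return out


def _validate_labels(pattern: Pattern, side: Side) -> None:
    if pattern == Pattern.UNILATERAL:
        if side not in (Side.LEFT, Side.RIGHT):
            raise SliceError("unilateral pattern requires side left or right")
    elif side != Side.NONE:
        raise SliceError(f"pattern {pattern.value} must have side none")


def make_phantom_slice(
    level: Level,
    pattern: Pattern,
    side: Side = Side.NONE,
    contrast: float = 0.4,
    rng_seed: int = 0,
    geometry: PhantomGeometry = DEFAULT_GEOMETRY,
) -> SpectSlice:
    """Build one seeded phantom slice.

    ``contrast`` in [0, 1] is the fractional count reduction in the
    hypoperfused hemisphere(s); it is ignored for the normal pattern.
    """
    level, pattern, side = Level(level), Pattern(pattern), Side(side)
    _validate_labels(pattern, side)
    if not 0.0 <= contrast <= 1.0:
        raise SliceError("contrast must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    fld = _expected_field(level, geometry, rng)
    fld = _apply_defect(fld, pattern, side, contrast)
    lo, hi = geometry.count_scale_range
    scale = rng.uniform(lo, hi) / max(fld.max(), 1e-9)
    counts = rng.poisson(scale * fld).astype(np.float64)
    pixels = ndimage.gaussian_filter(counts, geometry.post_smooth_sigma)
    return SpectSlice(pixels=pixels, level=level, pattern=pattern, side=side)


def make_neighbor(parent: SpectSlice, rng_seed: int = 0) -> SpectSlice:
    """Simulate the adjacent craniocaudal slice of ``parent``.

    The neighbor shares the parent's labels and gross structure but is
    warped by a smooth random displacement field (~1.5 px), rescaled in
    intensity, and re-noised with independent Poisson counts.
    """
    rng = np.random.default_rng(rng_seed)
    disp = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=(2, MATRIX_SIZE, MATRIX_SIZE)),
        sigma=(0, 8, 8),
    )
    for k in range(2):
        peak = np.abs(disp[k]).max()
        if peak > 0:
            disp[k] *= 1.5 / peak
    rows, cols = np.mgrid[0:MATRIX_SIZE, 0:MATRIX_SIZE].astype(np.float64)
    smooth = ndimage.gaussian_filter(parent.pixels, 0.7)
    warped = ndimage.map_coordinates(
        smooth, [rows + disp[0], cols + disp[1]], order=1, mode="nearest"
    )
    warped = np.clip(warped * rng.uniform(0.92, 1.08), 0.0, None)
    counts = rng.poisson(warped).astype(np.float64)
    pixels = ndimage.gaussian_filter(counts, 1.0)
    return SpectSlice(
        pixels=pixels, level=parent.level, pattern=parent.pattern, side=parent.side
    )


def build_dataset(
    composition: Optional[DatasetComposition] = None,
    rng_seed: int = 0,
    contrast_range: tuple[float, float] = (0.3, 0.55),
    geometry: PhantomGeometry = DEFAULT_GEOMETRY,
) -> list[SpectSlice]:
    """Generate a labelled phantom dataset matching ``composition``.

    Defect side for unilateral slices is assigned at random (50/50); the
    defect contrast is drawn per slice from ``contrast_range``.  Each slice
    gets a craniocaudal neighbor attached.
    """
    if composition is None:
        composition = DatasetComposition.table1()
    root = np.random.SeedSequence(rng_seed)
    slices: list[SpectSlice] = []
    for (level, pattern), n in sorted(
        composition.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        if n == 0:
            continue
        cell_ss = root.spawn(1)[0]
        child_seeds = cell_ss.generate_state(3 * n, dtype=np.uint32)
        rng = np.random.default_rng(cell_ss)
        for i in range(n):
            if Pattern(pattern) == Pattern.UNILATERAL:
                side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
            else:
                side = Side.NONE
            contrast = float(rng.uniform(*contrast_range))
            s = make_phantom_slice(
                Level(level),
                Pattern(pattern),
                side,
                contrast,
                rng_seed=int(child_seeds[3 * i]),
                geometry=geometry,
            )
            s.neighbor = make_neighbor(s, rng_seed=int(child_seeds[3 * i + 1]))
            slices.append(s)
    return slices
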