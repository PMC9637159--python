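"""Slice persistence: NIfTI files with a CSV manifest, optional PNG previews.

Each slice is stored as a single-slice NIfTI volume (lossless float data)
named ``{level}_{pattern}_{index:04d}.nii``; the accompanying
``manifest.csv`` records file, level, pattern, side and the neighbor file
(if a craniocaudal neighbor is attached).  PNG previews are 8-bit and
quantize the [0, max] range, so they are for inspection only.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .slices import MATRIX_SIZE, Level, Pattern, Side, SliceError, SpectSlice

__all__ = ["IOError_", "write_slices", "read_slices", "write_png"]

MANIFEST = "manifest.csv"


class IOError_(ValueError):
    """Raised for missing manifests, bad shapes or unknown labels."""


def _save_nifti(pixels: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(pixels.astype(np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return data.reshape(data.shape[0], data.shape[1])


def write_png(pixels: np.ndarray, path: Path) -> None:
    """8-bit preview of a nonnegative slice ([0, max] -> 0..255)."""
    peak = float(pixels.max())
    scaled = np.zeros_like(pixels) if peak <= 0 else pixels / peak
    Image.fromarray((scaled * 255).round().astype(np.uint8)).save(path)


def write_slices(
    slices: Sequence[SpectSlice], path: str | Path, png_previews: bool = False
) -> Path:
    """Write slices + manifest to a directory; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counters: dict[tuple[Level, Pattern], int] = {}
    rows = []
    for s in slices:
        idx = counters.get((s.level, s.pattern), 0)
        counters[(s.level, s.pattern)] = idx + 1
        stem = f"{s.level.value}_{s.pattern.value}_{idx:04d}"
        _save_nifti(s.pixels, path / f"{stem}.nii")
        neighbor_file = ""
        if s.neighbor is not None:
            neighbor_file = f"{stem}_nb.nii"
            _save_nifti(s.neighbor.pixels, path / neighbor_file)
        if png_previews:
            write_png(s.pixels, path / f"{stem}.png")
        rows.append(
            {
                "file": f"{stem}.nii",
                "level": s.level.value,
                "pattern": s.pattern.value,
                "side": s.side.value,
                "neighbor_file": neighbor_file,
            }
        )
    manifest = path / MANIFEST
    pd.DataFrame(
        rows, columns=["file", "level", "pattern", "side", "neighbor_file"]
    ).to_csv(manifest, index=False)
    return manifest


def read_slices(path: str | Path) -> list[SpectSlice]:
    """Read a slice directory written by :func:`write_slices`."""
    path = Path(path)
    manifest = path / MANIFEST
    if not manifest.exists():
        if path.exists() and any(path.iterdir()):
            raise IOError_(f"missing {MANIFEST} in {path}")
        warnings.warn(f"no slices found in {path}", stacklevel=2)
        return []
    df = pd.read_csv(manifest, keep_default_na=False)
    slices = []
    for row in df.itertuples(index=False):
        try:
            level = Level(row.level)
            pattern = Pattern(row.pattern)
            side = Side(row.side)
        except ValueError as exc:
            raise IOError_(f"unknown label in manifest row {row}: {exc}") from exc
        pixels = _load_nifti(path / row.file)
        if pixels.shape != (MATRIX_SIZE, MATRIX_SIZE):
            raise IOError_(f"{row.file}: expected 64x64, got {pixels.shape}")
        try:
            s = SpectSlice(pixels=pixels, level=level, pattern=pattern, side=side)
            if row.neighbor_file:
                s.neighbor = SpectSlice(
                    pixels=_load_nifti(path / row.neighbor_file),
                    level=level,
                    pattern=pattern,
                    side=side,
                )
        except SliceError as exc:
            raise IOError_(f"{row.file}: {exc}") from exc
        slices.append(s)
    return slices
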