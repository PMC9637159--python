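"""Fidelity evaluation of real versus generated slice sets.

The protocol compares simple physiologically meaningful statistics
between real and generated images, per perfusion pattern:

* MC — mean counts, the arithmetic mean over all 4096 pixels;
* LR — left/right hemisphere count ratio, sum of the left-half columns
  over the sum of the right-half columns;
* pixelwise mean and standard-deviation maps across a set, the SD map
  summarizing within-pattern diversity.

Group differences are assessed with one-way ANOVA across the real /
variant-A / variant-B groups, followed by Tukey HSD pairwise comparisons
(real vs A, real vs B).  Images are max-normalized before metrics so real
counts and tanh-range outputs live on the same [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .slices import Pattern, SpectSlice

__all__ = [
    "EvaluationError",
    "FidelityReport",
    "mean_counts",
    "lr_ratio",
    "pixelwise_maps",
    "anova_compare",
    "fidelity_report",
    "group_by_pattern",
]

HALF = 32


class EvaluationError(ValueError):
    pass


def mean_counts(image: np.ndarray) -> float:
    """Mean pixel intensity over the whole slice (no brain mask)."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise EvaluationError("image contains non-finite pixels")
    return float(image.mean())


def lr_ratio(image: np.ndarray, radiological: bool = False) -> float:
    """Left/right hemisphere count ratio.

    By default the left hemisphere is the left half of the stored array
    (columns 0-31).  With ``radiological=True`` the display convention
    (patient left on image right) is assumed and the halves swap.
    """
    image = np.asarray(image, dtype=np.float64)
    left = float(image[:, :HALF].sum())
    right = float(image[:, HALF:].sum())
    if radiological:
        left, right = right, left
    if right <= 0:
        raise EvaluationError("right-hemisphere sum must be positive")
    return left / right


def pixelwise_maps(images: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and (population) standard-deviation maps of a set."""
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if len(images) < 2:
        raise EvaluationError("pixelwise maps need at least 2 images")
    stack = np.stack(images)
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


def sd_summary(images: Sequence[np.ndarray]) -> float:
    """Average of the pixelwise SD map — the scalar diversity summary."""
    _, sd = pixelwise_maps(images)
    return float(sd.mean())


def anova_compare(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, P)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise EvaluationError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise EvaluationError("each group needs at least two values")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    if within == 0 and not np.allclose(means, means[0]):
        raise EvaluationError("zero within-group variance with unequal means")
    if within == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


SliceSet = Union[Sequence[SpectSlice], Mapping[Pattern, Sequence[np.ndarray]]]


def group_by_pattern(images: SliceSet) -> dict[Pattern, list[np.ndarray]]:
    """Group a slice set by perfusion pattern, max-normalizing each image."""
    groups: dict[Pattern, list[np.ndarray]] = {}
    if isinstance(images, Mapping):
        items = [
            (Pattern(p), np.asarray(im, dtype=np.float64))
            for p, ims in images.items()
            for im in ims
        ]
    else:
        items = [(s.pattern, s.pixels) for s in images]
    for pattern, im in items:
        peak = im.max()
        if peak <= 0:
            raise EvaluationError("cannot normalize an all-zero image")
        groups.setdefault(pattern, []).append(im / peak)
    return groups


@dataclass
class FidelityReport:
    """Per-pattern MC/LR distributions, maps and real-vs-generated tests."""

    mc: dict = field(default_factory=dict)  # (pattern, source) -> list[float]
    lr: dict = field(default_factory=dict)
    mean_maps: dict = field(default_factory=dict)  # (pattern, source) -> 64x64
    sd_maps: dict = field(default_factory=dict)
    sd_average: dict = field(default_factory=dict)  # (pattern, source) -> float
    group_sizes: dict = field(default_factory=dict)
    anova: dict = field(default_factory=dict)  # (metric, pattern) -> (F, P)
    pvalues: dict = field(default_factory=dict)  # (metric, pattern, source) -> P
    alpha: float = 0.05

    @property
    def significant(self) -> dict:
        return {k: p < self.alpha for k, p in self.pvalues.items()}


def fidelity_report(
    real_set: SliceSet, gen_a_set: SliceSet, gen_b_set: SliceSet,
    radiological: bool = False,
) -> FidelityReport:
    """Compare real, variant-A and variant-B image sets per pattern.

    For each of the three patterns and each metric (MC, LR) an omnibus
    one-way ANOVA across the three sources is computed, followed by Tukey
    HSD P-values for real-vs-A and real-vs-B.
    """
    sources = {
        "real": group_by_pattern(real_set),
        "A": group_by_pattern(gen_a_set),
        "B": group_by_pattern(gen_b_set),
    }
    for name, groups in sources.items():
        missing = [p for p in Pattern if p not in groups or len(groups[p]) < 2]
        if missing:
            raise EvaluationError(
                f"set '{name}' lacks patterns: {[p.value for p in missing]}"
            )
    report = FidelityReport()
    for pattern in Pattern:
        per_source = {}
        for name, groups in sources.items():
            imgs = groups[pattern]
            mc = [mean_counts(im) for im in imgs]
            lr = [lr_ratio(im, radiological=radiological) for im in imgs]
            report.mc[(pattern, name)] = mc
            report.lr[(pattern, name)] = lr
            mean_map, sd_map = pixelwise_maps(imgs)
            report.mean_maps[(pattern, name)] = mean_map
            report.sd_maps[(pattern, name)] = sd_map
            report.sd_average[(pattern, name)] = float(sd_map.mean())
            report.group_sizes[(pattern, name)] = len(imgs)
            per_source[name] = (mc, lr)
        for mi, metric in enumerate(("mc", "lr")):
            triplet = [per_source[name][mi] for name in ("real", "A", "B")]
            report.anova[(metric, pattern)] = anova_compare(triplet)
            tukey = stats.tukey_hsd(*triplet)
            report.pvalues[(metric, pattern, "A")] = float(tukey.pvalue[0, 1])
            report.pvalues[(metric, pattern, "B")] = float(tukey.pvalue[0, 2])
    return report
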