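"""Contrast-enhanced CT quantification.

Mean Hounsfield density inside the tumour contour is measured on the
unenhanced and the post-contrast series, after restricting the analysis
to the density window -50 <= HU <= +350 (bounds inclusive).  The contour
is drawn on the contrast-enhanced series and copied to the plain series.
The relative necrotic volume is the fraction of contour voxels whose
post-contrast density falls below a hypodensity threshold; complete
hypodensity (fraction 1) raises a total-necrosis flag so downstream
correlation analyses can rerun with the outlier excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class HULimits:
    """Density window for whole-tumour analysis, inclusive at both ends."""

    lo: float = -50.0
    hi: float = 350.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("HU limits require lo < hi")


@dataclass
class CTStudy:
    """Paired pre/post-contrast HU volumes sharing one grid and contour."""

    pre: np.ndarray
    post: np.ndarray
    contour: np.ndarray
    voxel_spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        self.contour = np.asarray(self.contour, dtype=bool)
        if not (self.pre.shape == self.post.shape == self.contour.shape):
            raise ValueError("pre, post and contour must share one grid")


@dataclass(frozen=True)
class CTMeasures:
    mean_pre: float
    mean_post: float
    enhancement: float          # mean_post - mean_pre
    necrotic_fraction: float
    total_necrosis_flag: bool


def apply_hu_limits(volume: np.ndarray, contour: np.ndarray,
                    limits: HULimits = HULimits()) -> np.ndarray:
    """Voxels inside the contour whose density lies within the window."""
    volume = np.asarray(volume, dtype=float)
    contour = np.asarray(contour, dtype=bool)
    if volume.shape != contour.shape:
        raise ValueError("volume and contour shapes differ")
    return contour & (volume >= limits.lo) & (volume <= limits.hi)


def mean_hu(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean HU over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return float(np.asarray(volume, dtype=float)[mask].mean())


def necrotic_volume_fraction(study: CTStudy,
                             threshold: float = 50.0) -> tuple[float, bool]:
    """Relative necrotic volume on the post-contrast series.

    Fraction of contour voxels with post-contrast HU strictly below
    ``threshold``; the flag fires when the fraction is exactly 1
    (the whole tumour reads as necrotic).
    """
    n_contour = int(study.contour.sum())
    if n_contour == 0:
        raise ValueError("contour is empty")
    n_necrotic = int((study.contour & (study.post < threshold)).sum())
    fraction = n_necrotic / n_contour
    return fraction, fraction == 1.0


def contrast_enhancement(study: CTStudy, limits: HULimits = HULimits(),
                         necrosis_threshold: float = 50.0) -> CTMeasures:
    """Mean pre/post HU under the density window, plus necrotic volume.

    The contour (drawn on the enhanced series) is applied to both series;
    the window is applied to each volume's own densities, so each mean
    runs over its own in-range voxels.
    """
    pre_mask = apply_hu_limits(study.pre, study.contour, limits)
    post_mask = apply_hu_limits(study.post, study.contour, limits)
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("density window leaves no voxels on one series")
    m_pre = mean_hu(study.pre, pre_mask)
    m_post = mean_hu(study.post, post_mask)
    frac, flag = necrotic_volume_fraction(study, necrosis_threshold)
    return CTMeasures(mean_pre=m_pre, mean_post=m_post,
                      enhancement=m_post - m_pre,
                      necrotic_fraction=frac, total_necrosis_flag=flag)
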