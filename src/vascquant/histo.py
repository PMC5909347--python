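"""Histological reference quantification.

Microvessel density (MVD) is the number of CD-31-positively stained
structures per mm^2 of tissue section; embolised fluorescent beads are
counted per microscope field of view (FOV).  A "structure" is one
connected component of the thresholded stain channel (8-connectivity by
default) after removal of sub-minimum-area specks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure


@dataclass
class StainedSlide:
    """One digitised micrograph with physical pixel size (um/pixel)."""

    image: np.ndarray
    pixel_size: float              # um per pixel
    magnification: str = "20x"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.image.ndim not in (2, 3):
            raise ValueError("image must be 2-D grey or 3-channel")
        if self.image.ndim == 3 and self.image.shape[2] != 3:
            raise ValueError(f"unsupported channel count {self.image.shape[2]}")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding/labelling knobs for stain and bead detection.

    ``polarity`` states whether objects are darker ('dark', chromogenic
    stains) or brighter ('bright', fluorescence) than the threshold.
    """

    threshold: float = 0.5
    min_structure_area: int = 3    # pixels
    connectivity: Literal[4, 8] = 8
    polarity: Literal["dark", "bright"] = "dark"

    def __post_init__(self) -> None:
        if self.min_structure_area < 1:
            raise ValueError("min_structure_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class MVDResult:
    count: int
    area: float        # mm^2
    density: float     # count / mm^2


@dataclass(frozen=True)
class BeadCountResult:
    per_fov_counts: list[int]
    mean_per_fov: float


def _grey(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image.mean(axis=2)
    return image


def segment_stained_structures(slide: StainedSlide,
                               params: SegmentationParams = SegmentationParams()
                               ) -> np.ndarray:
    """Label image of stained structures (labels dense from 1).

    Connected components of the thresholded stain channel; components
    smaller than ``min_structure_area`` pixels are removed and labels
    re-densified.
    """
    grey = _grey(slide.image)
    if grey.size == 0:
        raise ValueError("empty image")
    binary = grey < params.threshold if params.polarity == "dark" \
        else grey > params.threshold
    conn = 1 if params.connectivity == 4 else 2
    labels = measure.label(binary, connectivity=conn)
    if params.min_structure_area > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= params.min_structure_area
        keep[0] = False
        labels = measure.label(keep[labels], connectivity=conn)
    return labels


def microvessel_density(labels: np.ndarray, pixel_size: float) -> MVDResult:
    """MVD from a label image: structure count per mm^2 of section."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    area_mm2 = labels.size * (pixel_size / 1000.0) ** 2
    if area_mm2 == 0:
        raise ValueError("zero tissue area")
    count = int(labels.max())
    return MVDResult(count=count, area=area_mm2, density=count / area_mm2)


def count_beads(fovs: Sequence[StainedSlide],
                params: SegmentationParams = SegmentationParams(polarity="bright")
                ) -> BeadCountResult:
    """Per-FOV bead counts and their mean (beads are bright blobs)."""
    if len(fovs) == 0:
        raise ValueError("at least one field of view is required")
    counts = [int(segment_stained_structures(f, params).max()) for f in fovs]
    return BeadCountResult(per_fov_counts=counts,
                           mean_per_fov=float(np.mean(counts)))
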