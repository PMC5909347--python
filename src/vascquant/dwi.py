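"""Diffusion/perfusion-separated ADC mapping from multi-b-value DWI.

The acquisition protocol samples b = 0, 50, 100, 150, 200, 250, 300, 500,
750 and 1000 s/mm^2.  Two apparent diffusion coefficients are derived per
voxel:

* ``ADC_diff`` — slope of the log-linear least-squares fit over the
  diffusion-dominated high-b subset {500, 750, 1000},
* ``ADC_perf`` — the perfusion-sensitive excess: the fit over the low-b
  subset {50, 100, 150} minus ``ADC_diff`` (negative differences clipped
  to zero by default).

Maps carry a validity mask (a voxel is invalid when any signal in the fit
subset is non-positive), can be resampled onto a reference grid, rendered
as 8-bit colour images, and summarised (min/mean/max) inside a propagated
tumour contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

LOW_B_SUBSET = (50.0, 100.0, 150.0)
HIGH_B_SUBSET = (500.0, 750.0, 1000.0)


class NoValidVoxelsError(ValueError):
    """ROI and validity mask have an empty intersection."""


@dataclass
class BValueStack:
    """4-D DWI signal indexed by b-value, with grid metadata.

    ``signal`` has shape ``grid_shape + (len(b_values),)``; ``affine``
    maps voxel indices to physical (mm) coordinates, defaulting to a
    scaling by ``voxel_spacing``.
    """

    signal: np.ndarray
    b_values: np.ndarray
    voxel_spacing: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.voxel_spacing = np.asarray(self.voxel_spacing, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, b)")
        if self.signal.shape[3] != self.b_values.size:
            raise ValueError("4th signal dimension must match len(b_values)")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_spacing) + [1.0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ADCMap:
    """Per-voxel apparent diffusion coefficient map (mm^2/s).

    ``valid`` marks voxels where the fit succeeded; ``values`` is finite
    wherever valid (invalid voxels hold 0).  Report tables print values in
    mm^2/s x 1e-6 — that scaling is presentation-only.
    """

    values: np.ndarray
    valid: np.ndarray
    b_subset: tuple[float, ...]
    kind: Literal["diff", "low", "perf"]
    voxel_spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.diag(list(np.asarray(self.voxel_spacing, float)) + [1.0])


@dataclass
class ROIMask:
    """Boolean region-of-interest mask with provenance and grid metadata."""

    mask: np.ndarray
    label: str = "tumour"
    voxel_spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine is None:
            self.affine = np.diag(list(np.asarray(self.voxel_spacing, float)) + [1.0])


@dataclass(frozen=True)
class ROIStats:
    minimum: float
    mean: float
    maximum: float
    n_voxels: int


@dataclass
class Colour8BitMap:
    """Per-slice 3-channel 8-bit rendering of an ADC map."""

    rgb: np.ndarray            # (x, y, z, 3) uint8
    index: np.ndarray          # (x, y, z) uint8 grey level before colormap
    window: tuple[float, float]
    colormap: str


def fit_adc_map(stack: BValueStack, b_subset: Sequence[float]) -> ADCMap:
    """Log-linear least-squares ADC over a b-value subset.

    Per voxel the ADC is minus the slope of the ordinary least-squares
    line of ``ln(signal)`` against ``b`` over ``b_subset`` (free
    intercept).  Voxels with any non-positive signal in the subset are
    marked invalid and carry value 0.
    """
    subset = np.asarray(sorted(b_subset), dtype=float)
    if subset.size < 2:
        raise ValueError("b_subset must contain at least two b-values")
    present = np.isin(subset, stack.b_values)
    if not present.all():
        raise ValueError(
            f"b-values {subset[~present].tolist()} not present in the stack")
    idx = [int(np.flatnonzero(stack.b_values == b)[0]) for b in subset]
    s = stack.signal[..., idx]
    valid = np.all(s > 0, axis=-1)
    logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), 0.0)
    bc = subset - subset.mean()
    denom = float(np.sum(bc * bc))
    slope = np.tensordot(logs, bc, axes=([-1], [0])) / denom
    values = np.where(valid, -slope, 0.0)
    kind = ("diff" if tuple(subset) == HIGH_B_SUBSET
            else "low" if tuple(subset) == LOW_B_SUBSET else "diff")
    return ADCMap(values=values, valid=valid, b_subset=tuple(subset),
                  kind=kind, voxel_spacing=stack.voxel_spacing,
                  affine=stack.affine)


def compute_adc_diff(stack: BValueStack,
                     b_subset: Sequence[float] = HIGH_B_SUBSET) -> ADCMap:
    """Diffusion-dominated ADC over the high-b subset {500, 750, 1000}."""
    m = fit_adc_map(stack, b_subset)
    return replace(m, kind="diff")


def compute_adc_perf(stack: BValueStack,
                     low_subset: Sequence[float] = LOW_B_SUBSET,
                     high_subset: Sequence[float] = HIGH_B_SUBSET,
                     clip_negative: bool = True) -> ADCMap:
    """Perfusion-sensitive ADC: low-b fit minus high-b fit.

    ``ADC_perf = ADC_low - ADC_diff`` per voxel; any single-exponential
    decay therefore yields 0 everywhere.  Negative differences (noise)
    are clipped to 0 unless ``clip_negative`` is False; validity is the
    conjunction of both fits' validity.
    """
    low = fit_adc_map(stack, low_subset)
    high = fit_adc_map(stack, high_subset)
    values = low.values - high.values
    if clip_negative:
        values = np.maximum(values, 0.0)
    valid = low.valid & high.valid
    return ADCMap(values=np.where(valid, values, 0.0), valid=valid,
                  b_subset=tuple(low.b_subset) + tuple(high.b_subset),
                  kind="perf", voxel_spacing=stack.voxel_spacing,
                  affine=stack.affine)


def _voxel_coords_on_reference(src_affine, ref_affine, ref_shape):
    """Source-grid voxel coordinates of every reference-grid voxel centre."""
    ref_idx = np.indices(ref_shape, dtype=float).reshape(3, -1)
    ones = np.ones((1, ref_idx.shape[1]))
    world = ref_affine @ np.vstack([ref_idx, ones])
    src = np.linalg.inv(src_affine) @ world
    return src[:3]


def resample_to_reference(adc_map: ADCMap, reference_affine: np.ndarray,
                          reference_shape: tuple[int, int, int],
                          reference_spacing: np.ndarray | None = None) -> ADCMap:
    """Resample a map onto a reference grid (registration by metadata).

    Values are interpolated linearly; invalidity is propagated
    conservatively (any contribution from an invalid or out-of-grid voxel
    invalidates the target voxel).  Identical grids pass through
    bit-identically.
    """
    reference_affine = np.asarray(reference_affine, dtype=float)
    if (tuple(reference_shape) == tuple(adc_map.values.shape)
            and np.array_equal(reference_affine, adc_map.affine)):
        return replace(adc_map, values=adc_map.values.copy(),
                       valid=adc_map.valid.copy())
    coords = _voxel_coords_on_reference(adc_map.affine, reference_affine,
                                        reference_shape)
    shp = np.asarray(adc_map.values.shape, dtype=float)
    inside = np.all((coords >= -0.5) & (coords <= (shp - 0.5)[:, None]), axis=0)
    if not inside.any():
        raise ValueError("reference grid does not overlap the map's physical extent")
    values = ndimage.map_coordinates(adc_map.values, coords, order=1,
                                     mode="nearest").reshape(reference_shape)
    bad = ndimage.map_coordinates((~adc_map.valid).astype(float), coords,
                                  order=1, mode="constant", cval=1.0)
    valid = (bad < 1e-9).reshape(reference_shape) & inside.reshape(reference_shape)
    spacing = (np.asarray(reference_spacing, float) if reference_spacing is not None
               else np.linalg.norm(reference_affine[:3, :3], axis=0))
    return ADCMap(values=np.where(valid, values, 0.0), valid=valid,
                  b_subset=adc_map.b_subset, kind=adc_map.kind,
                  voxel_spacing=spacing, affine=reference_affine)


def propagate_contour(contour: ROIMask, target_affine: np.ndarray,
                      target_shape: tuple[int, int, int],
                      target_spacing: np.ndarray | None = None) -> ROIMask:
    """Copy a contour onto another grid by nearest-neighbour resampling.

    Membership is never interpolated fractionally: each target voxel takes
    the mask value of the nearest source voxel (outside the source grid it
    is background).
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if (tuple(target_shape) == tuple(contour.mask.shape)
            and np.array_equal(target_affine, contour.affine)):
        return replace(contour, mask=contour.mask.copy())
    coords = _voxel_coords_on_reference(contour.affine, target_affine,
                                        target_shape)
    shp = np.asarray(contour.mask.shape, dtype=float)
    inside = np.all((coords >= -0.5) & (coords <= (shp - 0.5)[:, None]), axis=0)
    if not inside.any():
        raise ValueError("target grid does not overlap the contour's physical extent")
    vals = ndimage.map_coordinates(contour.mask.astype(np.uint8), coords,
                                   order=0, mode="constant", cval=0)
    mask = (vals > 0).reshape(target_shape) & inside.reshape(target_shape)
    spacing = (np.asarray(target_spacing, float) if target_spacing is not None
               else np.linalg.norm(target_affine[:3, :3], axis=0))
    return ROIMask(mask=mask, label=contour.label, voxel_spacing=spacing,
                   affine=target_affine)


def roi_statistics(adc_map: ADCMap, roi: ROIMask) -> ROIStats:
    """Minimum / mean / maximum ADC over valid voxels inside the ROI."""
    if roi.mask.shape != adc_map.values.shape:
        raise ValueError("ROI and map shapes differ; propagate the contour first")
    sel = roi.mask & adc_map.valid
    if not sel.any():
        raise NoValidVoxelsError(
            f"no valid voxels inside ROI {roi.label!r}")
    vals = adc_map.values[sel]
    return ROIStats(minimum=float(vals.min()), mean=float(vals.mean()),
                    maximum=float(vals.max()), n_voxels=int(sel.sum()))


def render_8bit(adc_map: ADCMap, window: tuple[float, float] = (0.0, 3000e-6),
                colormap: str = "viridis") -> Colour8BitMap:
    """8-bit colour rendering of an ADC map.

    Values are clamped to ``window``, scaled linearly to grey levels
    0-255 (round half away from zero), then pushed through a matplotlib
    colormap.  Invalid voxels map to level 0.
    """
    import matplotlib
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must satisfy hi > lo")
    norm = np.clip((adc_map.values - lo) / (hi - lo), 0.0, 1.0)
    norm = np.where(adc_map.valid, norm, 0.0)
    index = np.floor(norm * 255.0 + 0.5).astype(np.uint8)  # half away from zero
    lut = (matplotlib.colormaps[colormap](np.arange(256) / 255.0)[:, :3]
           * 255.0 + 0.5).astype(np.uint8)
    return Colour8BitMap(rgb=lut[index], index=index, window=(lo, hi),
                         colormap=colormap)


def tumour_volume(roi: ROIMask, voxel_spacing: Sequence[float] | None = None) -> float:
    """Tumour volume in cm^3 from a voxel mask and spacing in mm."""
    spacing = np.asarray(voxel_spacing if voxel_spacing is not None
                         else roi.voxel_spacing, dtype=float)
    n = int(roi.mask.sum())
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * float(np.prod(spacing)) / 1000.0
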